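"""Exact genome mapping of collapsed reads.

Reads are placed by exact full-length string matching on both strands.  At
toy-genome scale this is the deterministic equivalent of the
seed-and-extend aligners used on real genomes; mismatch tolerance is an
explicit non-goal.

The index stores every k-mer of the forward genome as a 2-bit-encoded
integer in a sorted array; minus-strand hits are found by looking up the
reverse complement of the query, which preserves strand symmetry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import revcomp

DEFAULT_K = 18
DEFAULT_MAX_LOCI = 5

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

__all__ = ["Alignment", "GenomeIndex", "build_index", "map_read", "map_reads",
           "write_bed", "write_alignment_tsv"]


@dataclass
class Alignment:
    """Exact placement of a read: 0-based half-open genomic interval."""

    read_ref: str          # the insert sequence itself serves as the id
    contig: str
    start: int
    end: int
    strand: str            # "+" or "-"
    n_hits: int = 1        # genome-wide multiplicity of the read
    count: float = 1.0     # read count carried along for downstream weighting


class GenomeIndex:
    """Sorted k-mer index over one or more contigs."""

    def __init__(self, genome: dict[str, str] | str, k: int = DEFAULT_K):
        if k > 18:
            raise ValueError("k must be <= 18 (the shortest mappable read)")
        if isinstance(genome, str):
            genome = {"contig1": genome}
        self.k = k
        self.contigs: dict[str, str] = dict(genome)
        self._sorted: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for name, seq in self.contigs.items():
            kmers = self._kmer_codes(seq, k)
            order = np.argsort(kmers, kind="stable")
            self._sorted[name] = kmers[order]
            self._order[name] = order

    @staticmethod
    def _encode_seq(seq: str) -> np.ndarray:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        codes = np.full(arr.shape, -1, dtype=np.int64)
        for base, code in _CODE.items():
            codes[arr == ord(base)] = code
        return codes

    @classmethod
    def _kmer_codes(cls, seq: str, k: int) -> np.ndarray:
        codes = cls._encode_seq(seq)
        n = len(codes) - k + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        km = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for t in range(k):
            c = codes[t : t + n]
            km = km * 4 + np.where(c >= 0, c, 0)
            valid &= c >= 0
        km[~valid] = -1  # k-mers containing non-ACGT never match queries
        return km

    @staticmethod
    def encode_kmer(kmer: str) -> int:
        code = 0
        for c in kmer:
            v = _CODE.get(c)
            if v is None:
                return -1
            code = code * 4 + v
        return code

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (contig, position) occurrences of a k-mer on the forward
        strand, in ascending position order."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} nt")
        q = self.encode_kmer(kmer)
        hits = []
        for name in self.contigs:
            srt, order = self._sorted[name], self._order[name]
            lo = np.searchsorted(srt, q, side="left")
            hi = np.searchsorted(srt, q, side="right")
            hits.extend((name, int(p)) for p in sorted(order[lo:hi]))
        return hits if q >= 0 else []

    def _candidates(self, q: int, contig: str) -> np.ndarray:
        srt, order = self._sorted[contig], self._order[contig]
        lo = np.searchsorted(srt, q, side="left")
        hi = np.searchsorted(srt, q, side="right")
        return order[lo:hi]


def build_index(genome: dict[str, str] | str, k: int = DEFAULT_K) -> GenomeIndex:
    return GenomeIndex(genome, k)


def map_read(read, index: GenomeIndex,
             max_loci: int = DEFAULT_MAX_LOCI) -> list["Alignment"]:
    """All exact full-length placements of one read on both strands.

    ``read`` may be a plain sequence string or a CollapsedRead.  ``n_hits``
    is the total multiplicity; callers exclude reads with
    ``n_hits > max_loci`` from hairpin discovery (they stay usable for
    fractional quantification).
    """
    seq = read if isinstance(read, str) else read.insert_seq
    count = 1.0 if isinstance(read, str) else float(read.count)
    k = index.k
    if len(seq) < k:
        return []
    alns: list[Alignment] = []
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        q = index.encode_kmer(query[:k])
        if q < 0:
            continue
        for contig in index.contigs:
            g = index.contigs[contig]
            for p in index._candidates(q, contig):
                p = int(p)
                if g[p : p + len(query)] == query:
                    alns.append(Alignment(read_ref=seq, contig=contig,
                                          start=p, end=p + len(query),
                                          strand=strand, count=count))
    alns.sort(key=lambda a: (a.contig, a.start, a.strand))
    for a in alns:
        a.n_hits = len(alns)
    return alns


def map_reads(reads, index: GenomeIndex,
              max_loci: int = DEFAULT_MAX_LOCI) -> dict[str, list[Alignment]]:
    """Map a collection of reads; returns {insert_seq: alignments}."""
    out: dict[str, list[Alignment]] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.insert_seq
        if seq not in out:
            out[seq] = map_read(read, index, max_loci)
    return out


def write_bed(alignments: list[Alignment], path) -> None:
    """BED6: 0-based half-open, score column carries the read count."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.read_ref}"
                     f"\t{a.count:g}\t{a.strand}\n")


def write_alignment_tsv(alignments: list[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tcontig\tstart\tend\tstrand\tn_hits\tcount\n")
        for a in alignments:
            fh.write(f"{a.read_ref}\t{a.contig}\t{a.start}\t{a.end}"
                     f"\t{a.strand}\t{a.n_hits}\t{a.count:g}\n")
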