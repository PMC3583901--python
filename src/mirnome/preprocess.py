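"""Raw-read preprocessing: adapter/poly(A) trimming, length selection, collapsing.

The cloning protocol puts a fixed synthetic adapter at the 5' end of every
read and a poly(A) tail at the 3' end.  Preprocessing removes both, keeps
inserts of 18-30 nt (the mappable small-RNA size range), and collapses
identical inserts into counted records.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

MIN_INSERT_LEN = 18
MAX_INSERT_LEN = 30

__all__ = [
    "CollapsedRead", "PreprocessStats",
    "trim_adapter", "trim_polya", "length_filter", "collapse",
    "preprocess_reads", "read_sequences", "write_collapsed_fasta",
    "write_collapsed_tsv",
]


@dataclass
class CollapsedRead:
    """A distinct insert sequence with its read count in one library."""

    insert_seq: str
    count: int
    read_ids: list[str] | None = None


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_no_adapter: int = 0
    n_length_filtered: int = 0
    n_kept: int = 0
    n_unique: int = 0


def trim_adapter(read: str, adapter: str, min_prefix_match: int = 6) -> str:
    """Remove a 5' adapter occurrence.

    Accepts the full adapter as read prefix, or (for reads that start
    mid-adapter) a suffix of the adapter of length >= ``min_prefix_match``.
    The longest match wins; a read without a detectable adapter is
    returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if read.startswith(adapter):
        return read[len(adapter):]
    for n in range(len(adapter) - 1, min_prefix_match - 1, -1):
        if read.startswith(adapter[-n:]):
            return read[n:]
    return read


def trim_polya(read: str, min_tail: int = 4) -> str:
    """Strip a terminal poly(A) run of at least ``min_tail`` bases.

    Shorter terminal A-runs are retained: they are indistinguishable from
    genuine genomic 3' adenosines, and the ligated tails are longer.
    """
    if min_tail < 3:
        raise ValueError("min_tail must be >= 3")
    stripped = read.rstrip("A")
    if len(read) - len(stripped) >= min_tail:
        return stripped
    return read


def length_filter(reads: list[str], min_len: int = MIN_INSERT_LEN,
                  max_len: int = MAX_INSERT_LEN) -> list[str]:
    """Keep inserts in the mappable 18-30 nt range."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse(reads: list[str]) -> list[CollapsedRead]:
    """One record per distinct insert, ordered by descending count then
    lexicographically; counts sum to the input read count."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    return [CollapsedRead(insert_seq=s, count=c)
            for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def preprocess_reads(raw_reads: list[str], adapter: str,
                     min_prefix_match: int = 6, min_tail: int = 4,
                     keep_no_adapter: bool = False
                     ) -> tuple[list[CollapsedRead], PreprocessStats]:
    """Full preprocessing of one library.

    Reads whose adapter cannot be located are discarded by default
    (``keep_no_adapter`` passes them through untrimmed instead).
    """
    stats = PreprocessStats(n_input=len(raw_reads))
    inserts: list[str] = []
    for read in raw_reads:
        read = read.upper().replace("U", "T")
        trimmed = trim_adapter(read, adapter, min_prefix_match)
        if trimmed == read:  # trimming always shortens, so this means no match
            stats.n_no_adapter += 1
            if not keep_no_adapter:
                continue
        inserts.append(trim_polya(trimmed, min_tail))
    kept = length_filter(inserts)
    stats.n_length_filtered = len(inserts) - len(kept)
    stats.n_kept = len(kept)
    collapsed = collapse(kept)
    stats.n_unique = len(collapsed)
    return collapsed, stats


def read_sequences(path) -> list[str]:
    """Sequences from a FASTQ or FASTA file (format sniffed from content)."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]


def write_collapsed_fasta(collapsed: list[CollapsedRead], path) -> None:
    """miRDeep-style ``>seq{i}_x{count}`` FASTA."""
    with open(path, "w") as fh:
        for i, cr in enumerate(collapsed):
            fh.write(f">seq{i + 1}_x{cr.count}\n{cr.insert_seq}\n")


def write_collapsed_tsv(collapsed: list[CollapsedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("insert_seq\tcount\n")
        for cr in collapsed:
            fh.write(f"{cr.insert_seq}\t{cr.count}\n")
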