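"""Synthetic small-RNA sequencing data with planted ground truth.

Generates a toy genome in which known miRNA hairpins, novel (unannotated)
hairpins, tRNA/rRNA/snRNA-snoRNA loci, repeat regions and unannotated
degraded-fragment loci are planted without overlap, then simulates
454-style small-RNA libraries over three condition groups (non-failing
heart NF, dilated cardiomyopathy DCM, hypertrophic cardiomyopathy HCM).

Each simulated read reproduces the cloning-library structure: a fixed 5'
adapter, an insert drawn from a planted locus, and a 3' poly(A) tail.  The
default class mix approximates a deep-sequenced cardiac library: ~22% of
mapped reads from repeat regions and ~28% from the non-miRNA ncRNA
fraction, of which tRNA fragments make up ~78%.

Hairpin loci are constructed so that the planted mature and star sequences
form a duplex with 2-nt 3' overhangs on both strands (the Drosha/Dicer
processing signature), the stem carries a few G:U wobbles on the star arm
(so mature reads map uniquely rather than also hitting their own reverse
complement), and read 3' ends never fall on a genomic A (so poly(A)-tail
trimming is unambiguous and the simulate->preprocess round trip is exact).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# fractions of reads per class; repeat and the tRNA share of ncRNA follow the
# composition of a deep-sequenced cardiac small-RNA library
DEFAULT_CLASS_FRACTIONS = {
    "known_mirna": 0.31,
    "trna": 0.28 * 0.78,
    "rrna": 0.28 * 0.12,
    "snrna_snorna": 0.28 * 0.10,
    "repeat": 0.22,
    "novel_hairpin": 0.02,
    "other": 0.17,
}

GROUPS = ("NF", "DCM", "HCM")

_CLASS_TO_ANNOTATION = {
    "known_mirna": "miRNA_known",
    "trna": "tRNA",
    "rrna": "rRNA",
    "snrna_snorna": "snoRNA",
    "repeat": "repeat",
}


@dataclass
class SimulationConfig:
    """Parameters of the toy genome and read libraries.

    ``group_profiles`` maps group -> {locus_id: expression multiplier};
    loci absent from a group's map have multiplier 1.  The default profile
    makes the last five known miRNAs HCM-specific (6x in HCM) and the three
    before those DCM-specific, giving the differential stages true
    positives to find.
    """

    genome_length: int = 5_000_000
    n_known_mirnas: int = 30
    n_novel_hairpins: int = 20
    n_trna_loci: int = 40
    n_rrna_loci: int = 6
    n_sn_sno_loci: int = 20
    n_repeat_regions: int = 80
    n_other_loci: int = 60
    group_profiles: dict[str, dict[str, float]] | None = None
    libraries_per_group: int = 3
    reads_per_library: int = 50_000
    adapter_seq: str = "ATCGTAGGCACCTGAAA"
    polya_len_range: tuple[int, int] = (6, 12)
    insert_len_range: tuple[int, int] = (15, 30)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    p_modal_start: float = 0.9      # 5'-end homogeneity of hairpin reads
    star_fraction: float = 0.10     # fraction of hairpin reads from the star arm
    substitution_rate: float = 0.0
    n_disease_specific: tuple[int, int] = (3, 5)   # (DCM-, HCM-specific) knowns
    disease_multiplier: float = 6.0
    contig_name: str = "toy1"
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()
        if self.group_profiles is None:
            self.group_profiles = self._default_profiles()

    def validate(self) -> None:
        counts = [self.n_known_mirnas, self.n_novel_hairpins, self.n_trna_loci,
                  self.n_rrna_loci, self.n_sn_sno_loci, self.n_repeat_regions,
                  self.n_other_loci, self.libraries_per_group,
                  self.reads_per_library]
        if any(c < 0 for c in counts):
            raise ValueError("all locus/library counts must be >= 0")
        lo, hi = self.insert_len_range
        if not (10 <= lo <= hi <= 40):
            raise ValueError("insert_len_range must lie within [10, 40]")
        if not self.adapter_seq:
            raise ValueError("adapter_seq must be non-empty")
        # rough sizing check; placement retries give the hard guarantee
        footprint = 600 * sum([self.n_known_mirnas, self.n_novel_hairpins,
                               self.n_trna_loci, self.n_rrna_loci,
                               self.n_sn_sno_loci, self.n_repeat_regions,
                               self.n_other_loci])
        if self.genome_length < footprint:
            raise ValueError(
                f"genome_length {self.genome_length} too small for "
                f"~{footprint} bases of planted loci plus spacing")

    def _default_profiles(self) -> dict[str, dict[str, float]]:
        n_dcm, n_hcm = self.n_disease_specific
        known_ids = [f"known-{i + 1:04d}" for i in range(self.n_known_mirnas)]
        hcm = known_ids[-n_hcm:] if n_hcm else []
        dcm = known_ids[-(n_hcm + n_dcm): -n_hcm or None] if n_dcm else []
        m = self.disease_multiplier
        return {
            "NF": {},
            "DCM": {lid: m for lid in dcm},
            "HCM": {lid: m for lid in hcm},
        }

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_profiles)

    @property
    def library_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups
                for i in range(self.libraries_per_group)]

    def group_of(self, library_id: str) -> str:
        return library_id.rsplit("_", 1)[0]


@dataclass
class GroundTruth:
    """Planted loci, their sequences, and expected per-library read counts."""

    loci: pd.DataFrame            # one row per planted locus
    true_expression: pd.DataFrame  # locus x library expected read counts
    genome: str
    contig: str

    def loci_of_class(self, klass: str) -> pd.DataFrame:
        return self.loci[self.loci["klass"] == klass]


# ---------------------------------------------------------------------------
# genome construction


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _build_hairpin(rng: np.random.Generator,
                   arm_len: int = 35, loop_len: int = 12,
                   mature_offset: int = 4, mature_len: int = 22
                   ) -> tuple[str, int, int, int, int]:
    """Precursor with a planted mature/star duplex.

    Returns (precursor, mature_start, mature_end, star_start, star_end) in
    precursor coordinates.  The stem is arm + loop + revcomp(arm) with
    three G:U wobbles introduced on the star arm inside the duplex, which
    keeps the fold a clean stem-loop while breaking the exact
    reverse-complement identity of the mature sequence.
    """
    m0, mlen = mature_offset, mature_len
    while True:
        arm = list(_random_dna(rng, arm_len))
        # poly(A)-trimming safety: mature 3' end and star 3' end (which pairs
        # with arm positions 1-2) must not be A after taking complements
        if arm[m0 + mlen - 1] == "A":
            arm[m0 + mlen - 1] = "CGT"[rng.integers(3)]
        for p in (1, 2):
            if arm[p] == "T":          # complement would be A
                arm[p] = "ACG"[rng.integers(3)]
        wobble_sites = [i for i in range(m0 + 2, m0 + mlen - 2)
                        if arm[i] in "GT"]
        if len(wobble_sites) >= 3:
            break
    arm = "".join(arm)
    # loop drawn from {A, C}: neither base pairs with itself or the other
    # (Watson-Crick or wobble), so the loop cannot fold internally and the
    # precursor reliably collapses to the "[]" stem-loop shape
    loop = "".join("AC"[i] for i in rng.integers(0, 2, size=loop_len))
    star_arm = list(revcomp(arm))
    L = 2 * arm_len + loop_len
    chosen = rng.choice(len(wobble_sites), size=3, replace=False)
    for ci in sorted(chosen):
        i = wobble_sites[ci]
        partner = L - 1 - i                      # precursor coordinate
        j = partner - (arm_len + loop_len)       # index into star_arm
        star_arm[j] = "T" if arm[i] == "G" else "G"   # G:U / U:G wobble
    precursor = arm + loop + "".join(star_arm)

    # 2-nt 3' overhangs on both duplex strands: the star 3' end extends two
    # bases past the partner of the mature 5' end (and symmetrically)
    mature_start, mature_end = m0, m0 + mlen
    star_end = L + 2 - m0
    star_start = star_end - mlen
    return precursor, mature_start, mature_end, star_start, star_end


def build_genome(config: SimulationConfig
                 ) -> tuple[str, pd.DataFrame, GroundTruth]:
    """Toy genome with non-overlapping planted loci.

    Returns (genome sequence, annotation table, ground truth).  Known
    miRNAs are annotated with class ``miRNA_known``; novel hairpins and
    "other" loci are deliberately left unannotated (they are what the
    discovery stage must find or reject).
    """
    rng = np.random.default_rng(config.seed)
    genome = list(_random_dna(rng, config.genome_length))

    plan: list[tuple[str, str, int]] = []  # (class, locus_id, length)
    spec = [
        ("known_mirna", config.n_known_mirnas, None),
        ("novel_hairpin", config.n_novel_hairpins, None),
        ("trna", config.n_trna_loci, (70, 90)),
        ("rrna", config.n_rrna_loci, (110, 160)),
        ("snrna_snorna", config.n_sn_sno_loci, (70, 150)),
        ("repeat", config.n_repeat_regions, (250, 400)),
        ("other", config.n_other_loci, (120, 200)),
    ]
    short = {"known_mirna": "known", "novel_hairpin": "novel", "trna": "trna",
             "rrna": "rrna", "snrna_snorna": "snsno", "repeat": "repeat",
             "other": "other"}
    for klass, n, lrange in spec:
        for i in range(n):
            length = 82 if lrange is None else int(rng.integers(*lrange))
            plan.append((klass, f"{short[klass]}-{i + 1:04d}", length))

    # non-overlapping placement with a spacing margin, bounded retries
    margin = 150
    placed: list[tuple[int, int]] = []
    starts = np.array([], dtype=np.int64)
    ends = np.array([], dtype=np.int64)
    rows = []
    for klass, locus_id, length in plan:
        for attempt in range(2000):
            s = int(rng.integers(0, config.genome_length - length))
            e = s + length
            lo = np.searchsorted(starts, e + margin)
            hi = np.searchsorted(ends, s - margin, side="right")
            if lo == hi:  # no interval within margin
                break
        else:
            raise ValueError("could not place all loci: genome too small")
        idx = int(np.searchsorted(starts, s))
        starts = np.insert(starts, idx, s)
        ends = np.insert(ends, idx, e)
        placed.append((s, e))

        strand = "+" if (klass not in ("known_mirna", "novel_hairpin")
                         or rng.random() < 0.5) else "-"
        row = {"locus_id": locus_id, "klass": klass, "contig": config.contig_name,
               "start": s, "end": e, "strand": strand, "name": locus_id,
               "mature_start": -1, "mature_end": -1,
               "star_start": -1, "star_end": -1,
               "mature_seq": "", "star_seq": ""}
        if klass in ("known_mirna", "novel_hairpin"):
            pre, m0, m1, s0, s1 = _build_hairpin(rng)
            seq = pre if strand == "+" else revcomp(pre)
            genome[s:e] = list(seq)
            if strand == "+":
                row.update(mature_start=s + m0, mature_end=s + m1,
                           star_start=s + s0, star_end=s + s1)
            else:
                row.update(mature_start=e - m1, mature_end=e - m0,
                           star_start=e - s1, star_end=e - s0)
            row["mature_seq"] = pre[m0:m1]
            row["star_seq"] = pre[s0:s1]
        rows.append(row)

    genome = "".join(genome)
    loci = pd.DataFrame(rows)

    # expression weights: lognormal per locus, shared across libraries
    weights = pd.Series(rng.lognormal(0.0, 1.0, size=len(loci)),
                        index=loci["locus_id"])
    # name the median-expressed known miRNA hsa-miR-195 (the abundance
    # threshold reference), the rest hsa-miR-sim-*
    known = loci[loci["klass"] == "known_mirna"]
    if len(known):
        kw = weights[known["locus_id"]]
        ref_locus = kw.sort_values().index[len(kw) // 2]
        names = {lid: f"hsa-miR-sim-{i + 1:03d}"
                 for i, lid in enumerate(known["locus_id"])}
        names[ref_locus] = "hsa-miR-195"
        loci.loc[loci["klass"] == "known_mirna", "name"] = (
            loci.loc[loci["klass"] == "known_mirna", "locus_id"].map(names))

    # per-library expected counts: class fraction split by weight, times
    # group multiplier, renormalised per library
    base = pd.Series(0.0, index=loci["locus_id"])
    for klass, frac in config.class_fractions.items():
        sel = loci.loc[loci["klass"] == klass, "locus_id"]
        if len(sel):
            w = weights[sel]
            base[sel] = frac * w / w.sum()
    base = base / base.sum() if base.sum() > 0 else base

    expr = {}
    for lib in config.library_ids:
        prof = config.group_profiles[config.group_of(lib)]
        p = base * pd.Series({lid: prof.get(lid, 1.0) for lid in base.index})
        p = p / p.sum() if p.sum() > 0 else p
        expr[lib] = p * config.reads_per_library
    true_expression = pd.DataFrame(expr)

    ann_rows = []
    for _, r in loci.iterrows():
        ann_class = _CLASS_TO_ANNOTATION.get(r["klass"])
        if ann_class is None:
            continue
        if r["klass"] == "known_mirna":
            # annotate the whole precursor so both arms (mature and star
            # reads) classify as known miRNA and stay out of discovery
            ann_rows.append((r["contig"], r["start"], r["end"],
                             r["strand"], ann_class, r["name"]))
        else:
            ann_rows.append((r["contig"], r["start"], r["end"],
                             r["strand"], ann_class, r["name"]))
    annotations = pd.DataFrame(
        ann_rows, columns=["contig", "start", "end", "strand", "klass", "name"])

    truth = GroundTruth(loci=loci, true_expression=true_expression,
                        genome=genome, contig=config.contig_name)
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# read simulation


def _library_rng(config: SimulationConfig, library_id: str) -> np.random.Generator:
    tag = zlib.crc32(library_id.encode()) % (2**31)
    return np.random.default_rng([config.seed % (2**31), tag])


def _hairpin_insert(rng: np.random.Generator, genome: str, strand: str,
                    m_start: int, m_end: int, p_modal: float) -> str:
    """Insert from a mature/star interval: 5' jitter, fixed 3' end."""
    jitter = 0
    if rng.random() >= p_modal:
        jitter = -1 if rng.random() < 0.5 else 1
    if strand == "+":
        s = m_start + jitter
        return genome[s:m_end]
    e = m_end - jitter
    return revcomp(genome[m_start:e])


def _fragment_insert(rng: np.random.Generator, genome: str,
                     start: int, end: int, len_range: tuple[int, int]) -> str:
    """Random degradation fragment with a non-A 3' end.

    Lengths are drawn from the mappable 18-30 nt part of the insert range
    so that the configured class fractions are realised among mapped
    reads, which is what library-composition figures report.
    """
    lo, hi = max(len_range[0], 18), len_range[1]
    for _ in range(50):
        ln = int(rng.integers(lo, hi + 1))
        if end - start <= ln:
            s = start
            ln = end - start
        else:
            s = int(rng.integers(start, end - ln + 1))
        e = s + ln
        while e > s + lo and genome[e - 1] == "A":
            e -= 1
        if e - s >= lo and genome[e - 1] != "A":
            return genome[s:e]
    return genome[start:start + lo]  # degenerate locus; accept as-is


def simulate_reads(truth: GroundTruth, library_id: str, group: str,
                   config: SimulationConfig) -> list[str]:
    """One library of raw reads: adapter + insert + poly(A) tail.

    Insert counts per locus are multinomial with probabilities proportional
    to the ground-truth expected expression of the library, so per-library
    totals equal ``reads_per_library`` exactly.
    """
    if group not in config.group_profiles:
        raise ValueError(f"unknown group {group!r}; "
                         f"known: {sorted(config.group_profiles)}")
    if library_id not in truth.true_expression.columns:
        raise ValueError(f"library {library_id!r} absent from ground truth")
    rng = _library_rng(config, library_id)
    expected = truth.true_expression[library_id]
    total = expected.sum()
    if config.reads_per_library == 0 or total == 0:
        return []
    p = (expected / total).to_numpy()
    counts = rng.multinomial(config.reads_per_library, p)

    loci = truth.loci.set_index("locus_id")
    genome = truth.genome
    tails_lo, tails_hi = config.polya_len_range
    reads: list[str] = []
    for locus_id, c in zip(expected.index, counts):
        if c == 0:
            continue
        r = loci.loc[locus_id]
        is_hairpin = r["klass"] in ("known_mirna", "novel_hairpin")
        for _ in range(int(c)):
            if is_hairpin:
                from_star = rng.random() < config.star_fraction
                if from_star:
                    ins = _hairpin_insert(rng, genome, r["strand"],
                                          int(r["star_start"]), int(r["star_end"]),
                                          config.p_modal_start)
                else:
                    ins = _hairpin_insert(rng, genome, r["strand"],
                                          int(r["mature_start"]), int(r["mature_end"]),
                                          config.p_modal_start)
            else:
                ins = _fragment_insert(rng, genome, int(r["start"]),
                                       int(r["end"]), config.insert_len_range)
            tail = "A" * int(rng.integers(tails_lo, tails_hi + 1))
            read = config.adapter_seq + ins + tail
            if config.substitution_rate > 0:
                read = _mutate(rng, read, config.substitution_rate)
            reads.append(read)
    return reads


def _mutate(rng: np.random.Generator, read: str, rate: float) -> str:
    arr = list(read)
    for i in range(len(arr)):
        if rng.random() < rate:
            arr[i] = "ACGT"[rng.integers(4)]
    return "".join(arr)


def simulate_all_libraries(truth: GroundTruth, config: SimulationConfig
                           ) -> dict[str, list[str]]:
    return {lib: simulate_reads(truth, lib, config.group_of(lib), config)
            for lib in config.library_ids}


# ---------------------------------------------------------------------------
# file output


def write_genome_fasta(genome: str, path, contig: str = "toy1",
                       width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i : i + width] + "\n")


def write_fastq(reads: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i + 1}\n{r}\n+\n{'I' * len(r)}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    truth.loci.to_csv(path, sep="\t", index=False)
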