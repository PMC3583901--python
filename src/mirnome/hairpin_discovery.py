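"""De-novo miRNA hairpin discovery from discovery-gated alignments.

Overlapping same-strand reads are grouped into blocks; each block of
plausible precursor-arm size is embedded in sliding windows of 80, 100 and
120 nt which are folded and kept when they form a single stem-loop
(abstract shape ``"[]"``) with the read block on one arm.  Read-pattern
features (read counts and lengths, 5'/3'-end heterogeneity, GC content,
the Drosha/Dicer processing signature, randfold significance) drive a
rule-based assignment of three confidence levels, after which candidates
are split into known and novel against the miRNA annotation and
deduplicated to one call per locus.

The paper trail for miRNA discovery pipelines names these features but
rarely their thresholds; the defaults in ``DiscoveryThresholds`` were
chosen to separate clean planted positives from degraded-fragment
negatives and are all configuration-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import Alignment
from .rna_structure import (FoldResult, abstract_shape, fold, pair_table,
                            prune_short_helices, randfold_p)
from .synthetic_data import revcomp

__all__ = ["ReadBlock", "HairpinCandidate", "DiscoveryThresholds",
           "build_blocks", "candidate_windows", "locate_arm",
           "dicer_signature", "classify_confidence", "split_known_novel",
           "dedup_candidates", "discover_hairpins",
           "start_heterogeneity", "end_heterogeneity"]


@dataclass
class DiscoveryThresholds:
    window_sizes: tuple[int, ...] = (80, 100, 120)
    window_step: int = 10
    max_block_len: int = 120          # longer blocks cannot be one precursor arm
    min_precursor_len: int = 50       # two ~22-nt arms plus a loop
    arm_frac: float = 0.8             # fraction of block bases defining an arm
    confident_min_reads: int = 10
    candidate_min_reads: int = 2
    median_len_range: tuple[int, int] = (20, 24)
    randfold_confident: float = 0.05
    randfold_candidate: float = 0.10
    gc_range: tuple[float, float] = (0.2, 0.8)
    max_start_heterogeneity: float = 0.2   # sharp 5' ends (Drosha cut)
    overhang_target: int = 2               # 3' overhang of the duplex, +/- 1
    overhang_slack: int = 1
    n_shuffles: int = 100
    max_loci: int = 5                 # multi-mapper ceiling for discovery


@dataclass
class ReadBlock:
    """Cluster of mutually overlapping same-strand alignments."""

    contig: str
    start: int
    end: int
    strand: str
    alignments: list[Alignment]

    @property
    def total_count(self) -> float:
        return sum(a.count for a in self.alignments)


@dataclass
class HairpinCandidate:
    contig: str
    strand: str
    window_start: int
    window_end: int
    window_size: int
    fold: FoldResult
    arm: str                  # 5p / 3p / loop / spanning / none
    block_start: int
    block_end: int
    n_reads: float
    median_read_len: float
    start_heterogeneity: float
    end_heterogeneity: float
    gc_content: float
    dicer_overhang: bool
    randfold_p: float | None = None
    confidence: str = "non_confident"
    status: str = "novel"
    candidate_id: str = ""


# ---------------------------------------------------------------------------
# read blocks


def build_blocks(alignments: list[Alignment]) -> list[ReadBlock]:
    """Single sweep merging same-strand alignments that overlap by >= 1 bp.

    Abutting half-open intervals ([10,32) and [32,54)) do not overlap and
    form separate blocks; antisense read stacks always form their own
    blocks.
    """
    blocks: list[ReadBlock] = []
    keyed: dict[tuple[str, str], list[Alignment]] = {}
    for a in alignments:
        keyed.setdefault((a.contig, a.strand), []).append(a)
    for (contig, strand) in sorted(keyed):
        alns = sorted(keyed[(contig, strand)], key=lambda a: (a.start, a.end))
        cur: list[Alignment] = []
        cur_end = -1
        for a in alns:
            if cur and a.start < cur_end:
                cur.append(a)
                cur_end = max(cur_end, a.end)
            else:
                if cur:
                    blocks.append(ReadBlock(contig, cur[0].start, cur_end,
                                            strand, cur))
                cur = [a]
                cur_end = a.end
        if cur:
            blocks.append(ReadBlock(contig, cur[0].start, cur_end, strand, cur))
    return blocks


# ---------------------------------------------------------------------------
# windows and window-local geometry


def candidate_windows(block: ReadBlock, genome: dict[str, str],
                      sizes: tuple[int, ...] = (80, 100, 120),
                      step: int = 10) -> list[tuple[str, int, int, int]]:
    """(window_seq, start, end, size) tuples covering the block.

    For each size the windows slide in ``step``-nt increments over all
    placements that contain the whole block; windows that would extend
    past the contig are discarded.  Minus-strand blocks yield
    reverse-complemented window sequences (small-RNA sense).
    """
    contig_seq = genome[block.contig]
    bl = block.end - block.start
    out = []
    for s in sizes:
        if bl > s:
            continue
        for j in range((s - bl) // step + 1):
            ws = block.end - s + j * step
            we = ws + s
            if ws < 0 or we > len(contig_seq):
                continue
            seq = contig_seq[ws:we]
            if block.strand == "-":
                seq = revcomp(seq)
            out.append((seq, ws, we, s))
    return out


def _local(pos: int, ws: int, we: int, strand: str) -> int:
    """Genomic position -> window-local small-RNA-sense coordinate."""
    return pos - ws if strand == "+" else we - 1 - pos


def _read_ends_local(a: Alignment, ws: int, we: int, strand: str) -> tuple[int, int]:
    """(5' start, 3' end) of a read in window-local coordinates, inclusive."""
    if strand == "+":
        return a.start - ws, a.end - 1 - ws
    return we - a.end, we - 1 - a.start


def _weighted_modal(values: list[int], weights: list[float]) -> tuple[int, float]:
    agg: dict[int, float] = {}
    for v, w in zip(values, weights):
        agg[v] = agg.get(v, 0.0) + w
    modal = min(agg, key=lambda v: (-agg[v], v))
    return modal, agg[modal]


def start_heterogeneity(block: ReadBlock) -> float:
    """1 - (weighted fraction of reads sharing the modal 5' start)."""
    starts = [(a.start if block.strand == "+" else a.end - 1)
              for a in block.alignments]
    weights = [a.count for a in block.alignments]
    _, modal_w = _weighted_modal(starts, weights)
    return 1.0 - modal_w / sum(weights)


def end_heterogeneity(block: ReadBlock) -> float:
    ends = [(a.end - 1 if block.strand == "+" else a.start)
            for a in block.alignments]
    weights = [a.count for a in block.alignments]
    _, modal_w = _weighted_modal(ends, weights)
    return 1.0 - modal_w / sum(weights)


def _innermost_pair(pairs: dict[int, int]) -> tuple[int, int] | None:
    opens = [i for i, j in pairs.items() if i < j]
    if not opens:
        return None
    li = max(opens)
    return li, pairs[li]


def locate_arm(block: ReadBlock, fold_result: FoldResult,
               window: tuple[int, int], arm_frac: float = 0.8) -> str:
    """Assign the block to the 5' arm, 3' arm or loop of a stem-loop.

    Requires >= ``arm_frac`` of block bases on one side of the terminal
    loop (delimited by the innermost base pair); anything else is
    ``spanning``.
    """
    ws, we = window
    pairs = pair_table(prune_short_helices(fold_result.dot_bracket))
    inner = _innermost_pair(pairs)
    if inner is None:
        return "none"
    li, ri = inner
    ls = _local(block.start, ws, we, block.strand)
    le = _local(block.end - 1, ws, we, block.strand)
    ls, le = min(ls, le), max(ls, le) + 1          # local half-open interval
    n = le - ls
    in5 = max(0, min(le, li + 1) - ls)
    in3 = max(0, le - max(ls, ri))
    inloop = max(0, min(le, ri) - max(ls, li + 1))
    if in5 >= arm_frac * n:
        return "5p"
    if in3 >= arm_frac * n:
        return "3p"
    if inloop >= arm_frac * n:
        return "loop"
    return "spanning"


def _partner_with_slack(pairs: dict[int, int], pos: int, max_slack: int = 3
                        ) -> int | None:
    """Pairing partner of a position, sliding 3' over small bulges."""
    for delta in range(max_slack + 1):
        if pos + delta in pairs:
            return pairs[pos + delta] + delta
    return None


def dicer_signature(block: ReadBlock, opposite: list[Alignment],
                    fold_result: FoldResult, window: tuple[int, int],
                    thresholds: DiscoveryThresholds | None = None) -> bool:
    """Read-stack evidence of Drosha/Dicer processing.

    Requires homogeneous 5' ends (start heterogeneity <= 0.2) and, when
    reads exist on the opposite arm, a mature/star duplex with ~2-nt 3'
    overhangs on both strands as implied by the fold's base pairing.  With
    no opposite-arm reads the 5'-sharpness criterion decides alone.
    """
    th = thresholds or DiscoveryThresholds()
    if start_heterogeneity(block) > th.max_start_heterogeneity:
        return False
    if not opposite:
        return True
    ws, we = window
    pairs = pair_table(prune_short_helices(fold_result.dot_bracket))

    ends = [_read_ends_local(a, ws, we, block.strand) for a in block.alignments]
    w = [a.count for a in block.alignments]
    m5, _ = _weighted_modal([e[0] for e in ends], w)
    m3, _ = _weighted_modal([e[1] for e in ends], w)

    o_ends = [_read_ends_local(a, ws, we, block.strand) for a in opposite]
    ow = [a.count for a in opposite]
    s5, _ = _weighted_modal([e[0] for e in o_ends], ow)
    s3, _ = _weighted_modal([e[1] for e in o_ends], ow)

    lo = th.overhang_target - th.overhang_slack
    hi = th.overhang_target + th.overhang_slack
    q = _partner_with_slack(pairs, m5)
    if q is None or not (lo <= s3 - q <= hi):
        return False
    r = _partner_with_slack(pairs, s5)
    if r is None or not (lo <= m3 - r <= hi):
        return False
    return True


# ---------------------------------------------------------------------------
# classification


def classify_confidence(cand: HairpinCandidate,
                        thresholds: DiscoveryThresholds | None = None,
                        has_homolog: bool = False) -> str:
    """Rule-based confidence assignment.

    confident: stem-loop shape, block on one arm, >= 10 reads with miRNA-like
    lengths (median 20-24 nt), Dicer signature, randfold p <= 0.05 and
    non-extreme GC.  candidate: stem-loop shape, block on one arm, >= 2
    reads and either randfold p <= 0.1 or a Dicer signature (homology
    evidence promotes candidate to confident).  Everything else is
    non_confident.
    """
    th = thresholds or DiscoveryThresholds()
    shape_ok = cand.fold.shape == "[]"
    arm_ok = cand.arm in ("5p", "3p")
    p = cand.randfold_p
    lo_len, hi_len = th.median_len_range
    lo_gc, hi_gc = th.gc_range
    if (shape_ok and arm_ok
            and cand.n_reads >= th.confident_min_reads
            and lo_len <= cand.median_read_len <= hi_len
            and cand.dicer_overhang
            and p is not None and p <= th.randfold_confident
            and lo_gc <= cand.gc_content <= hi_gc):
        return "confident"
    if (shape_ok and arm_ok
            and cand.n_reads >= th.candidate_min_reads
            and ((p is not None and p <= th.randfold_candidate)
                 or cand.dicer_overhang)):
        return "confident" if has_homolog else "candidate"
    return "non_confident"


def split_known_novel(candidates: list[HairpinCandidate],
                      known_annotations, min_reciprocal: float = 0.5
                      ) -> list[HairpinCandidate]:
    """status = known iff the candidate's mature-arm (block) interval has
    >= 50% reciprocal overlap with an annotated miRNA on the same strand."""
    from .annotation import AnnotationIndex
    if not isinstance(known_annotations, AnnotationIndex):
        known_annotations = AnnotationIndex(known_annotations)
    for cand in candidates:
        status = "novel"
        for row in known_annotations.overlapping(cand.contig, cand.block_start,
                                                 cand.block_end):
            if row["klass"] != "miRNA_known" or row["strand"] != cand.strand:
                continue
            olap = (min(cand.block_end, row["end"])
                    - max(cand.block_start, row["start"]))
            if (olap >= min_reciprocal * (cand.block_end - cand.block_start)
                    and olap >= min_reciprocal * (row["end"] - row["start"])):
                status = "known"
                break
        cand.status = status
    return candidates


def dedup_candidates(candidates: list[HairpinCandidate]
                     ) -> list[HairpinCandidate]:
    """One reported candidate per locus.

    Candidates whose windows overlap on the same contig and strand (all
    window sizes over one block, and the mature/star blocks of one
    hairpin) form a locus cluster; the representative has the lowest
    randfold p, tie-broken by most reads then smallest window.
    """
    clusters: list[list[HairpinCandidate]] = []
    for cand in sorted(candidates,
                       key=lambda c: (c.contig, c.strand, c.window_start)):
        if (clusters
                and clusters[-1][0].contig == cand.contig
                and clusters[-1][0].strand == cand.strand
                and cand.window_start < max(c.window_end for c in clusters[-1])):
            clusters[-1].append(cand)
        else:
            clusters.append([cand])

    def rank(c: HairpinCandidate):
        return (c.randfold_p if c.randfold_p is not None else 1.0,
                -c.n_reads, c.window_size)

    out = []
    for i, cluster in enumerate(clusters):
        best = min(cluster, key=rank)
        best.candidate_id = f"hairpin-{i + 1:04d}"
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# top-level discovery


def _gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def extract_hairpin_component(window_fold: FoldResult, block_local: tuple[int, int],
                              min_len: int = 50, min_overlap_frac: float = 0.8
                              ) -> tuple[int, int] | None:
    """Local interval of the top-level stem-loop containing the read block.

    A window usually carries flanking sequence that folds into extra
    helices, so the window structure as a whole is rarely a single
    stem-loop.  This picks the outermost helix component that covers the
    block (>= ``min_overlap_frac`` of its bases) and is long enough to be
    a precursor; the caller refolds that trimmed interval and keeps it
    only if it forms the ``"[]"`` shape on its own.
    """
    db = prune_short_helices(window_fold.dot_bracket)
    pairs = pair_table(db)
    ls, le = block_local

    def containing_pair(lo: int, hi: int) -> tuple[int, int] | None:
        i = lo
        while i < hi:
            if db[i] == "(":
                j = pairs[i]
                olap = min(le, j + 1) - max(ls, i)
                if olap >= min_overlap_frac * (le - ls):
                    return i, j
                i = j + 1
            else:
                i += 1
        return None

    # descend through enclosing helices (window flanks may pair around the
    # precursor) until the subtree below is a single stem-loop
    lo, hi = 0, len(db)
    while True:
        cp = containing_pair(lo, hi)
        if cp is None:
            return None
        p, q = cp
        if q + 1 - p < min_len:
            return None
        if abstract_shape(db[p : q + 1]) == "[]":
            return p, q + 1
        lo, hi = p + 1, q


def discover_hairpins(alignments: list[Alignment], genome: dict[str, str] | str,
                      thresholds: DiscoveryThresholds | None = None,
                      seed: int = 0,
                      known_annotations=None,
                      homology: dict[str, bool] | None = None
                      ) -> list[HairpinCandidate]:
    """Run block building, window folding, feature extraction and
    confidence classification over discovery-gated alignments.

    Returns the deduplicated candidate list (one call per locus), with
    known/novel status when ``known_annotations`` is given.  ``homology``
    optionally maps candidate block keys ``"contig:start-end"`` to a
    homolog-present flag that can promote a candidate to confident.
    """
    th = thresholds or DiscoveryThresholds()
    if isinstance(genome, str):
        genome = {"contig1": genome}
    usable = [a for a in alignments if a.n_hits <= th.max_loci]
    blocks = build_blocks(usable)
    blocks = [b for b in blocks if b.end - b.start <= th.max_block_len]

    by_strand: dict[tuple[str, str], list[ReadBlock]] = {}
    for b in blocks:
        by_strand.setdefault((b.contig, b.strand), []).append(b)

    candidates: list[HairpinCandidate] = []
    randfold_cache: dict[tuple, float] = {}
    for block in blocks:
        n_reads = block.total_count
        lens = np.repeat([a.end - a.start for a in block.alignments],
                         [max(int(round(a.count)), 1) for a in block.alignments])
        median_len = float(np.median(lens)) if len(lens) else 0.0
        s_het = start_heterogeneity(block)
        e_het = end_heterogeneity(block)

        block_cands: list[HairpinCandidate] = []
        fallback: HairpinCandidate | None = None
        seen_precursors: set[tuple[int, int]] = set()
        for seq, ws, we, size in candidate_windows(block, genome,
                                                   th.window_sizes,
                                                   th.window_step):
            fr = fold(seq)
            if fr.shape == "[]":
                ps, pe, pfold = ws, we, fr
            else:
                # trim the window to the stem-loop component holding the block
                ls = _local(block.start, ws, we, block.strand)
                le = _local(block.end - 1, ws, we, block.strand)
                ls, le = min(ls, le), max(ls, le) + 1
                comp = extract_hairpin_component(fr, (ls, le),
                                                 th.min_precursor_len,
                                                 th.arm_frac)
                if comp is None:
                    if fallback is None or fr.score < fallback.fold.score:
                        fallback = HairpinCandidate(
                            contig=block.contig, strand=block.strand,
                            window_start=ws, window_end=we, window_size=size,
                            fold=fr, arm="none",
                            block_start=block.start, block_end=block.end,
                            n_reads=n_reads, median_read_len=median_len,
                            start_heterogeneity=s_het, end_heterogeneity=e_het,
                            gc_content=_gc_content(seq), dicer_overhang=False)
                    continue
                a, b = comp
                if block.strand == "+":
                    ps, pe = ws + a, ws + b
                else:
                    ps, pe = we - b, we - a
                pfold = fold(seq[a:b])
                if pfold.shape != "[]":
                    continue
            if (ps, pe) in seen_precursors:
                continue
            seen_precursors.add((ps, pe))
            cand = HairpinCandidate(
                contig=block.contig, strand=block.strand,
                window_start=ps, window_end=pe, window_size=size,
                fold=pfold, arm="none",
                block_start=block.start, block_end=block.end,
                n_reads=n_reads, median_read_len=median_len,
                start_heterogeneity=s_het, end_heterogeneity=e_het,
                gc_content=_gc_content(pfold.sequence), dicer_overhang=False)
            cand.arm = locate_arm(block, pfold, (ps, pe), th.arm_frac)
            opposite = [a for ob in by_strand[(block.contig, block.strand)]
                        if ob is not block and ob.start >= ps and ob.end <= pe
                        for a in ob.alignments]
            cand.dicer_overhang = dicer_signature(block, opposite, pfold,
                                                  (ps, pe), th)
            if (cand.arm in ("5p", "3p")
                    and n_reads >= th.candidate_min_reads):
                key = (block.contig, block.strand, ps, pe)
                if key not in randfold_cache:
                    rng = np.random.default_rng(
                        [seed % (2**31), ps % (2**31), pe % (2**31)])
                    randfold_cache[key] = randfold_p(pfold.sequence,
                                                     th.n_shuffles, rng).p_value
                cand.randfold_p = randfold_cache[key]
            block_cands.append(cand)

        if not block_cands and fallback is not None:
            block_cands = [fallback]
        for cand in block_cands:
            key = f"{cand.contig}:{cand.block_start}-{cand.block_end}"
            cand.confidence = classify_confidence(
                cand, th, has_homolog=bool(homology and homology.get(key)))
        candidates.extend(block_cands)

    if known_annotations is not None:
        split_known_novel(candidates, known_annotations)
    return dedup_candidates(candidates)
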