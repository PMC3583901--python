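"""RNA secondary-structure toolkit.

Folding here is a base-pair-weighted dynamic program (Nussinov-style energy
minimisation), not a full nearest-neighbour thermodynamic model.  Each
admissible pair contributes a fixed negative weight (G:C = -3, A:U = -2,
G:U = -1); two directly stacked pairs earn an additional bonus equal to
the sum of their pair weights (helix stacking), which rewards contiguous
stems over scattered pairs and gives the score enough granularity for the
randfold significance test to calibrate; hairpin loops must contain at
least ``MIN_LOOP`` unpaired bases.  The resulting score is a
minimum-free-energy proxy: more negative means more stable.  The optimum
is exact under this scoring scheme and is verified against exhaustive
enumeration in the test-suite.

The module also provides the RNAshapes-style abstract-shape reduction (a
single unbranched stem-loop collapses to ``"[]"``), the Altschul--Erickson
dinucleotide-preserving shuffle, and the randfold significance test (does a
sequence fold more stably than dinucleotide shuffles of itself?).

All sequence input accepts T and U interchangeably; output is in the DNA
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoldResult",
    "RandfoldResult",
    "fold",
    "fold_score",
    "fold_scores_batch",
    "abstract_shape",
    "prune_short_helices",
    "dinucleotide_shuffle",
    "dinucleotide_counts",
    "randfold_p",
    "pair_table",
]

MIN_LOOP = 3  # minimum unpaired bases enclosed by a pair

# pair weights (negative = stabilising); indices follow _CODE below
GC_SCORE = -3
AU_SCORE = -2
GU_SCORE = -1
_NO_PAIR = 30_000  # "cannot pair" sentinel, far above any real score

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_DECODE = "ACGT"

_PAIR_MATRIX = np.full((4, 4), _NO_PAIR, dtype=np.int16)
for _a, _b, _s in [
    ("G", "C", GC_SCORE), ("C", "G", GC_SCORE),
    ("A", "T", AU_SCORE), ("T", "A", AU_SCORE),
    ("G", "T", GU_SCORE), ("T", "G", GU_SCORE),
]:
    _PAIR_MATRIX[_CODE[_a], _CODE[_b]] = _s


@dataclass(frozen=True)
class FoldResult:
    """Optimal structure of one sequence under the pair-weight scoring."""

    sequence: str          # normalised to DNA alphabet
    dot_bracket: str
    score: int             # pair weights + stacking bonuses; 0 = unpaired
    shape: str             # abstract shape, e.g. "[]", "[][]", "_"


@dataclass(frozen=True)
class RandfoldResult:
    native_score: int
    n_shuffles: int
    p_value: float         # (1 + #{shuffle score <= native}) / (n_shuffles + 1)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _dp_tables(codes: np.ndarray):
    """Span-indexed DP tables for a batch of equal-length sequences.

    ``codes`` has shape (batch, n).  Returns (U, P, NO, pair_d) where, for
    span length s and start i, U[s][:, i] is the minimum score of
    seq[i:i+s]; P[s][:, i] the minimum given that (i, i+s-1) is paired
    (stacking bonus with any enclosing pair is added by the parent); and
    NO[s][:, i] the minimum given that (i, i+s-1) is not paired together.
    ``pair_d[d][:, i]`` is the pair weight of (i, i+d).
    """
    if codes.ndim == 1:
        codes = codes[None, :]
    batch, n = codes.shape
    span_min = MIN_LOOP + 2  # shortest pairable span
    pair_d: dict[int, np.ndarray] = {}
    for d in range(MIN_LOOP + 1, n):
        pair_d[d] = _PAIR_MATRIX[codes[:, : n - d], codes[:, d:]].astype(np.int32)

    zeros = [np.zeros((batch, n - s + 1), dtype=np.int32)
             for s in range(min(n + 1, span_min))]
    infs = [np.full((batch, n - s + 1), _NO_PAIR, dtype=np.int32)
            for s in range(min(n + 1, span_min))]
    U = list(zeros)
    NO = [z.copy() for z in zeros]
    P = list(infs)
    for s in range(span_min, n + 1):
        m = n - s + 1
        w_outer = pair_d[s - 1][:, :m]
        if s - 2 >= span_min:
            # inner interval [i+1, i+s-2]: either its ends pair (stack) or not
            stacked = (P[s - 2][:, 1 : 1 + m] + w_outer
                       + pair_d[s - 3][:, 1 : 1 + m])
            inner = np.minimum(stacked, NO[s - 2][:, 1 : 1 + m])
        else:
            inner = 0
        p = w_outer + inner
        np.minimum(p, _NO_PAIR, out=p)   # keep the unpairable sentinel flat

        no = U[s - 1][:, 1 : 1 + m].copy()           # base i unpaired
        for t in range(span_min, s):                 # i paired with i+t-1
            cand = P[t][:, :m] + U[s - t][:, t : t + m]
            np.minimum(no, cand, out=no)
        P.append(p)
        NO.append(no)
        U.append(np.minimum(p, no))
    return U, P, NO, pair_d


def fold_scores_batch(seqs: list[str] | np.ndarray) -> np.ndarray:
    """Minimum fold scores for a batch of equal-length sequences."""
    if isinstance(seqs, np.ndarray):
        codes = seqs
    else:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("batch folding requires equal-length sequences")
        codes = np.stack([_encode(s) for s in seqs])
    n = codes.shape[1]
    if n < MIN_LOOP + 2:
        return np.zeros(codes.shape[0], dtype=np.int64)
    U = _dp_tables(codes)[0]
    return U[n][:, 0].astype(np.int64)


def fold_score(seq: str) -> int:
    """Minimum fold score of one sequence (no traceback)."""
    return int(fold_scores_batch([_normalise(seq)])[0])


def fold(seq: str) -> FoldResult:
    """Fold one sequence, returning structure, score and abstract shape.

    Ties are broken deterministically: pairing the 5'-most base is
    preferred over leaving it unpaired, and among equal-scoring partners
    the shortest-range pair wins.
    """
    norm = _normalise(seq)
    if len(norm) < 10:
        raise ValueError("fold requires sequences of length >= 10")
    codes = _encode(norm)
    n = len(codes)
    U, P, NO, pair_d = _dp_tables(codes[None, :])
    span_min = MIN_LOOP + 2

    structure = ["."] * n
    # work items: (mode, start, span); mode "U" = unconstrained,
    # "P" = outer pair present, "N" = outer positions not paired together
    work = [("U", 0, n)]
    while work:
        mode, i, s = work.pop()
        while s >= span_min:
            if mode == "P":
                structure[i] = "("
                structure[i + s - 1] = ")"
                if s - 2 < span_min:
                    break
                w = int(pair_d[s - 1][0, i])
                inner = int(P[s][0, i]) - w
                stack_opt = (int(P[s - 2][0, i + 1]) + w
                             + int(pair_d[s - 3][0, i + 1]))
                if stack_opt == inner:
                    mode, i, s = "P", i + 1, s - 2
                else:
                    mode, i, s = "N", i + 1, s - 2
                continue
            target = int(U[s][0, i]) if mode == "U" else int(NO[s][0, i])
            if target == 0 and int(NO[s][0, i]) == 0:
                break  # nothing pairs in here
            # pairing base i is preferred, shortest range first
            t_hi = s + 1 if mode == "U" else s
            paired = False
            for t in range(span_min, t_hi):
                right = int(U[s - t][0, i + t]) if s - t > 0 else 0
                if int(P[t][0, i]) + right == target:
                    if s - t >= span_min:
                        work.append(("U", i + t, s - t))
                    mode, s = "P", t
                    paired = True
                    break
            if not paired:  # base i unpaired
                mode, i, s = "U", i + 1, s - 1
    db = "".join(structure)
    return FoldResult(sequence=norm, dot_bracket=db, score=int(U[n][0, 0]),
                      shape=abstract_shape(prune_short_helices(db)))


MIN_HELIX_FOR_SHAPE = 3  # stacked pairs; shorter helices are noise for shapes


def prune_short_helices(dot_bracket: str,
                        min_stack: int = MIN_HELIX_FOR_SHAPE) -> str:
    """Remove helices with fewer than ``min_stack`` contiguous stacked pairs.

    Base-pair maximisation happily forms isolated pairs and 2-stacks that
    no thermodynamic model would keep; pruning them before the shape
    abstraction makes shapes reflect the genuine helix architecture
    (canonical-structure convention).
    """
    pairs = pair_table(dot_bracket)
    out = list(dot_bracket)
    seen: set[int] = set()
    for i in sorted(p for p, q in pairs.items() if p < q):
        if i in seen:
            continue
        j = pairs[i]
        run = [(i, j)]
        while pairs.get(run[-1][0] + 1) == run[-1][1] - 1:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        seen.update(p for p, _ in run)
        if len(run) < min_stack:
            for p, q in run:
                out[p] = out[q] = "."
    return "".join(out)


def pair_table(dot_bracket: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def abstract_shape(dot_bracket: str) -> str:
    """Collapse a structure to its abstract shape.

    Every maximal unbranched helix nesting becomes one ``[]``; unpaired
    stretches are dropped; a structure with no pairs is ``"_"``.
    Multiloops nest: a stem enclosing two stems is ``[[][]]``.
    """
    pairs = pair_table(dot_bracket)

    def top_level(lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        i = lo
        while i < hi:
            if dot_bracket[i] == "(":
                j = pairs[i]
                out.append((i, j))
                i = j + 1
            else:
                i += 1
        return out

    def shape_of(p: int, q: int) -> str:
        inner = top_level(p + 1, q)
        while len(inner) == 1:  # unbranched continuation: merge helices
            p, q = inner[0]
            inner = top_level(p + 1, q)
        if not inner:
            return "[]"
        return "[" + "".join(shape_of(a, b) for a, b in inner) + "]"

    tops = top_level(0, len(dot_bracket))
    if not tops:
        return "_"
    return "".join(shape_of(p, q) for p, q in tops)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    s = _normalise(seq)
    for i in range(len(s) - 1):
        di = s[i : i + 2]
        counts[di] = counts.get(di, 0) + 1
    return counts


def dinucleotide_shuffle(seq: str, rng: np.random.Generator | int | None = None) -> str:
    """Uniform dinucleotide-preserving shuffle (Altschul-Erickson).

    The returned sequence has the same first nucleotide, last nucleotide
    and dinucleotide count vector as the input, sampled uniformly from all
    such sequences via random Eulerian paths on the dinucleotide multigraph.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = _normalise(seq)
    if len(s) < 3:
        raise ValueError("dinucleotide shuffle requires length >= 3")

    edges: dict[str, list[str]] = {}
    for i in range(len(s) - 1):
        edges.setdefault(s[i], []).append(s[i + 1])
    first, last = s[0], s[-1]
    vertices = list(edges)

    if all(len(set(v)) == 1 and k == v[0] for k, v in edges.items()):
        return s  # single-letter sequence: only one arrangement

    # sample a random "last edge" per vertex (except the terminal one) until
    # the chosen edges form an arborescence into the terminal vertex
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))]
                     for v in vertices if v != last}
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    walk_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_edge[v])
        walk_edges[v] = rest

    out = [first]
    ptr = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(s) - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    result = "".join(out)
    # defining property, asserted on every call
    assert result[0] == s[0] and result[-1] == s[-1]
    assert dinucleotide_counts(result) == dinucleotide_counts(s)
    return result


def randfold_p(seq: str, n_shuffles: int = 100,
               rng: np.random.Generator | int | None = None) -> RandfoldResult:
    """Significance of fold stability against dinucleotide shuffles.

    p = (1 + #{shuffles with score <= native}) / (n_shuffles + 1); ties
    count against significance (conservative).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    norm = _normalise(seq)
    native = fold_score(norm)
    shuffles = [dinucleotide_shuffle(norm, rng) for _ in range(n_shuffles)]
    scores = fold_scores_batch(shuffles)
    p = (1 + int(np.sum(scores <= native))) / (n_shuffles + 1)
    return RandfoldResult(native_score=native, n_shuffles=n_shuffles, p_value=p)
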