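"""Expression quantification, abundance/fold-change thresholds and group tests.

Counts are normalised to reads per million mapped reads (RPM).  The
abundance cutoff retains every miRNA whose pooled expression is at most
10% below that of hsa-miR-195 (i.e. >= 0.9x its pooled RPM); etiology
specificity requires at least 3-fold expression relative to both of the
other condition groups.  Group statistics are a one-way ANOVA across
NF/DCM/HCM on log10(RPM + pseudocount) followed by pairwise Student t
tests, with Benjamini-Hochberg q-values computed within each pairwise
comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIR195 = "hsa-miR-195"
CUTOFF_FRACTION = 0.9
FOLD_CHANGE_THRESHOLD = 3.0

PAIRWISE = [("DCM", "NF"), ("HCM", "NF"), ("HCM", "DCM")]

__all__ = ["ExpressionMatrix", "DifferentialResult", "normalize_rpm",
           "mir195_cutoff", "fold_changes", "etiology_specific",
           "group_tests", "table_s3_report", "MIR195"]


@dataclass
class ExpressionMatrix:
    """miRNA x library normalised counts with group labels per library."""

    values: pd.DataFrame           # rows = miRNA ids, columns = library ids
    groups: dict[str, str]         # library id -> group (NF/DCM/HCM)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"libraries without group labels: {sorted(missing)}")

    def libraries_of(self, group: str) -> list[str]:
        return [lib for lib in self.values.columns if self.groups[lib] == group]

    @property
    def group_names(self) -> list[str]:
        seen = []
        for lib in self.values.columns:
            g = self.groups[lib]
            if g not in seen:
                seen.append(g)
        return seen

    def group_means(self) -> pd.DataFrame:
        return pd.DataFrame({g: self.values[self.libraries_of(g)].mean(axis=1)
                             for g in self.group_names})


@dataclass
class DifferentialResult:
    """Per-miRNA group means, fold changes, tests and threshold flags."""

    table: pd.DataFrame


def normalize_rpm(raw_counts: pd.DataFrame, mapped_totals: pd.Series,
                  groups: dict[str, str]) -> ExpressionMatrix:
    """reads-per-million: raw * 1e6 / mapped total per library.

    Fractional multi-mapper weights in ``raw_counts`` pass straight
    through.
    """
    totals = mapped_totals.reindex(raw_counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        bad = totals.index[totals.isna() | (totals <= 0)].tolist()
        raise ValueError(f"non-positive or missing mapped totals for {bad}")
    return ExpressionMatrix(values=raw_counts * 1e6 / totals, groups=groups)


def mir195_cutoff(matrix: ExpressionMatrix, reference: str = MIR195,
                  fraction: float = CUTOFF_FRACTION) -> list[str]:
    """miRNAs whose pooled (mean over all libraries) RPM is >= 0.9x the
    pooled RPM of hsa-miR-195.  The reference itself always passes."""
    if reference not in matrix.values.index:
        raise ValueError(
            f"reference miRNA {reference!r} absent from the expression matrix; "
            "the abundance cutoff is defined relative to it")
    pooled = matrix.values.mean(axis=1)
    threshold = fraction * pooled[reference]
    return list(pooled.index[pooled >= threshold])


def fold_changes(matrix: ExpressionMatrix, pseudocount: float = 1.0
                 ) -> pd.DataFrame:
    """Pairwise group fold changes FC(A/B) = (mean_A + c)/(mean_B + c)."""
    means = matrix.group_means()
    out = means.rename(columns={g: f"mean_{g}" for g in means.columns})
    for a, b in PAIRWISE:
        if a in means.columns and b in means.columns:
            out[f"fc_{a.lower()}_{b.lower()}"] = (
                (means[a] + pseudocount) / (means[b] + pseudocount))
    return out


def etiology_specific(fc: pd.DataFrame,
                      threshold: float = FOLD_CHANGE_THRESHOLD,
                      require_both: bool = True) -> pd.DataFrame:
    """HCM-specific: >= 3-fold vs NF and (by default) also vs DCM;
    DCM-specific symmetric."""
    flags = pd.DataFrame(index=fc.index)
    hcm_nf = fc["fc_hcm_nf"] >= threshold
    dcm_nf = fc["fc_dcm_nf"] >= threshold
    hcm_dcm = fc["fc_hcm_dcm"] >= threshold
    dcm_hcm = 1.0 / fc["fc_hcm_dcm"] >= threshold
    if require_both:
        flags["hcm_specific"] = hcm_nf & hcm_dcm
        flags["dcm_specific"] = dcm_nf & dcm_hcm
    else:
        flags["hcm_specific"] = hcm_nf
        flags["dcm_specific"] = dcm_nf
    return flags


def group_tests(matrix: ExpressionMatrix, pseudocount: float = 1.0
                ) -> DifferentialResult:
    """ANOVA + pairwise Student t tests on log10(RPM + pseudocount).

    Rows with zero counts everywhere are reported with NaN statistics, as
    are comparisons with fewer than two libraries per group.  Rows with
    identical values in every group also yield NaN (no variance to test).
    BH adjustment is applied within each pairwise comparison family.
    """
    logv = np.log10(matrix.values + pseudocount)
    groups = {g: matrix.libraries_of(g) for g in matrix.group_names}
    out = fold_changes(matrix, pseudocount)
    nonzero = (matrix.values.sum(axis=1) > 0).to_numpy()

    arrays = [logv[libs].to_numpy() for libs in groups.values()]
    if all(a.shape[1] >= 2 for a in arrays) and len(arrays) >= 2:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows yield NaN, not noise
            f = stats.f_oneway(*arrays, axis=1)
        p_anova = np.where(nonzero, f.pvalue, np.nan)
    else:
        p_anova = np.full(len(logv), np.nan)
    out["p_anova"] = p_anova

    for a, b in PAIRWISE:
        col = f"p_{a.lower()}_{b.lower()}"
        if (a not in groups or b not in groups
                or len(groups[a]) < 2 or len(groups[b]) < 2):
            out[col] = np.nan
            out["q" + col[1:]] = np.nan
            continue
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = stats.ttest_ind(logv[groups[a]].to_numpy(),
                                logv[groups[b]].to_numpy(), axis=1)
        p = np.where(nonzero, t.pvalue, np.nan)
        out[col] = p
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out["q" + col[1:]] = q
    return DifferentialResult(table=out)


def table_s3_report(diff: DifferentialResult, matrix: ExpressionMatrix,
                    retained: list[str] | None = None,
                    literature: set[str] | None = None,
                    pseudocount: float = 1.0,
                    fc_threshold: float = FOLD_CHANGE_THRESHOLD
                    ) -> pd.DataFrame:
    """Supplementary-style per-miRNA report.

    One row per miRNA (restricted to the cutoff-retained set when given)
    with normalised reads per group, the three pairwise p-values and
    q-values, a literature flag and the etiology-specificity flags,
    sorted by pooled abundance descending.
    """
    tab = diff.table.copy()
    flags = etiology_specific(tab, threshold=fc_threshold)
    tab = tab.join(flags)
    tab["pooled_rpm"] = matrix.values.mean(axis=1)
    tab["passes_cutoff"] = (tab.index.isin(retained)
                            if retained is not None else True)
    tab["in_literature"] = (tab.index.isin(literature)
                            if literature is not None else False)
    if retained is not None:
        tab = tab.loc[tab.index.isin(retained)]
    tab = tab.sort_values("pooled_rpm", ascending=False)
    tab.index.name = "miRNA"
    return tab.reset_index()
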