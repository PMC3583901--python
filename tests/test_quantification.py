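"""RPM normalisation, abundance cutoff, fold-change rules, group statistics."""

import numpy as np
import pandas as pd
import pytest

from mirnome import quantification as qt

LIBS = ["NF_1", "NF_2", "NF_3", "DCM_1", "DCM_2", "DCM_3",
        "HCM_1", "HCM_2", "HCM_3"]
GROUPS = {lib: lib.rsplit("_", 1)[0] for lib in LIBS}


def matrix_from(values: dict, libs=None) -> qt.ExpressionMatrix:
    libs = libs or LIBS
    df = pd.DataFrame(values, index=libs).T
    return qt.ExpressionMatrix(values=df, groups={l: GROUPS[l] for l in libs})


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """q_i = min over k with p(k) >= p(i)-rank of p(k) * m / k."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = min(running, 1.0)
    return q


class TestNormalize:
    def test_rpm_scaling(self):
        raw = pd.DataFrame({"L1": [50.0]}, index=["mir-a"])
        mat = qt.normalize_rpm(raw, pd.Series({"L1": 1_000_000.0}),
                               {"L1": "NF"})
        assert mat.values.loc["mir-a", "L1"] == 50.0

    def test_zero_total_rejected(self):
        raw = pd.DataFrame({"L1": [5.0]}, index=["mir-a"])
        with pytest.raises(ValueError, match="mapped totals"):
            qt.normalize_rpm(raw, pd.Series({"L1": 0.0}), {"L1": "NF"})

    def test_column_sums_conserved(self, rng):
        raw = pd.DataFrame(rng.integers(0, 500, size=(30, 3)).astype(float),
                           columns=["a", "b", "c"])
        totals = pd.Series({"a": 40_000.0, "b": 55_000.0, "c": 61_000.0})
        mat = qt.normalize_rpm(raw, totals, {c: "NF" for c in "abc"})
        expected = raw.sum(axis=0) * 1e6 / totals
        pd.testing.assert_series_equal(mat.values.sum(axis=0), expected)

    def test_all_zero_row_stays_zero(self):
        raw = pd.DataFrame({"L1": [0.0], "L2": [0.0]}, index=["mir-z"])
        mat = qt.normalize_rpm(raw, pd.Series({"L1": 10.0, "L2": 10.0}),
                               {"L1": "NF", "L2": "DCM"})
        assert (mat.values.loc["mir-z"] == 0).all()


class TestMir195Cutoff:
    def test_boundary_inclusive(self):
        mat = matrix_from({"hsa-miR-195": [100.0] * 9,
                           "at-boundary": [90.0] * 9,
                           "below": [89.9] * 9})
        retained = qt.mir195_cutoff(mat)
        assert retained == ["hsa-miR-195", "at-boundary"]

    def test_reference_always_retained(self):
        mat = matrix_from({"hsa-miR-195": [10.0] * 9,
                           "huge": [10_000.0] * 9})
        assert "hsa-miR-195" in qt.mir195_cutoff(mat)

    def test_missing_reference_is_clear_error(self):
        mat = matrix_from({"mir-a": [1.0] * 9})
        with pytest.raises(ValueError, match="hsa-miR-195"):
            qt.mir195_cutoff(mat)

    def test_cutoff_monotone_in_fraction(self, rng):
        rows = {f"mir-{i}": rng.uniform(0, 200, 9) for i in range(40)}
        rows["hsa-miR-195"] = rng.uniform(50, 100, 9)
        mat = matrix_from(rows)
        sizes = [len(qt.mir195_cutoff(mat, fraction=f))
                 for f in (0.5, 0.9, 1.5, 3.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestFoldChanges:
    def test_exact_threefold_no_pseudocount(self):
        mat = matrix_from({"m": [10] * 3 + [30] * 3 + [10] * 3})
        fc = qt.fold_changes(mat, pseudocount=0.0)
        assert fc.loc["m", "fc_dcm_nf"] == pytest.approx(3.0)

    def test_equal_means_unity(self):
        mat = matrix_from({"m": [7.0] * 9})
        fc = qt.fold_changes(mat, pseudocount=1.0)
        assert fc.loc["m", "fc_hcm_nf"] == pytest.approx(1.0)

    def test_zero_denominator_finite_with_pseudocount(self):
        mat = matrix_from({"m": [0] * 3 + [0] * 3 + [99] * 3})
        fc = qt.fold_changes(mat, pseudocount=1.0)
        assert np.isfinite(fc.loc["m", "fc_hcm_nf"])
        assert fc.loc["m", "fc_hcm_nf"] == pytest.approx(100.0)


class TestEtiologySpecific:
    def test_specific_requires_both_comparisons(self):
        mat = matrix_from({"both": [10] * 3 + [10] * 3 + [90] * 3,
                           "fails-vs-dcm": [10] * 3 + [80] * 3 + [90] * 3})
        flags = qt.etiology_specific(qt.fold_changes(mat, pseudocount=0.0))
        assert flags.loc["both", "hcm_specific"]
        assert not flags.loc["fails-vs-dcm", "hcm_specific"]

    def test_nf_only_mode(self):
        mat = matrix_from({"m": [10] * 3 + [80] * 3 + [90] * 3})
        flags = qt.etiology_specific(qt.fold_changes(mat, pseudocount=0.0),
                                     require_both=False)
        assert flags.loc["m", "hcm_specific"]

    def test_flags_mutually_exclusive(self, rng):
        rows = {f"m{i}": rng.uniform(1, 100, 9) for i in range(50)}
        mat = matrix_from(rows)
        flags = qt.etiology_specific(qt.fold_changes(mat))
        assert not (flags["hcm_specific"] & flags["dcm_specific"]).any()

    def test_planted_specific_loci_recovered_exactly(self):
        """5 planted HCM-specific miRNAs among 60 nulls -> exactly 5 flagged."""
        rng = np.random.default_rng(2024)
        n_null, n_spec = 60, 5
        base = rng.lognormal(4, 1, n_null + n_spec)
        rows = {}
        for i, b in enumerate(base):
            mult = 6.0 if i >= n_null else 1.0
            lam = [b] * 6 + [b * mult] * 3
            rows[f"m{i}"] = rng.poisson(lam).astype(float)
        mat = matrix_from(rows)
        flags = qt.etiology_specific(qt.fold_changes(mat, pseudocount=1.0))
        flagged = set(flags.index[flags["hcm_specific"]])
        assert flagged == {f"m{i}" for i in range(n_null, n_null + n_spec)}


class TestGroupTests:
    def test_identical_values_yield_nan(self):
        mat = matrix_from({"flat": [5.0] * 9})
        tab = qt.group_tests(mat).table
        assert np.isnan(tab.loc["flat", "p_anova"])

    def test_bh_worked_example(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4 -> q = 0.04 for all
        q = brute_force_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_bh_matches_brute_force(self, rng):
        from statsmodels.stats.multitest import multipletests
        for n in (1, 5, 100, 1000):
            p = rng.uniform(size=n)
            q = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, brute_force_bh(p), atol=1e-12)

    def test_q_never_below_p(self, rng):
        rows = {f"m{i}": rng.poisson(50, 9).astype(float) for i in range(40)}
        tab = qt.group_tests(matrix_from(rows)).table
        for pair in ("dcm_nf", "hcm_nf", "hcm_dcm"):
            ok = tab[f"p_{pair}"].notna()
            assert (tab.loc[ok, f"q_{pair}"] >= tab.loc[ok, f"p_{pair}"] - 1e-12).all()

    def test_true_positive_has_smallest_q(self, rng):
        rows = {f"null{i}": rng.poisson(100, 9).astype(float)
                for i in range(100)}
        rows["hot"] = np.concatenate([rng.poisson(100, 3),
                                      rng.poisson(100, 3),
                                      rng.poisson(1000, 3)]).astype(float)
        tab = qt.group_tests(matrix_from(rows)).table
        assert tab["q_hcm_nf"].idxmin() == "hot"

    def test_insufficient_replicates_reported_as_na(self):
        libs = ["NF_1", "DCM_1", "HCM_1"]
        df = pd.DataFrame({l: [5.0] for l in libs}, index=["m"])
        mat = qt.ExpressionMatrix(values=df, groups={l: GROUPS[l] for l in libs})
        tab = qt.group_tests(mat).table
        assert np.isnan(tab.loc["m", "p_anova"])
        assert np.isnan(tab.loc["m", "p_dcm_nf"])


class TestReport:
    def test_columns_cover_the_three_comparisons(self):
        mat = matrix_from({"hsa-miR-195": [100.0] * 9, "m2": [200.0] * 9})
        diff = qt.group_tests(mat)
        rep = qt.table_s3_report(diff, mat)
        for col in ("p_dcm_nf", "p_hcm_nf", "p_hcm_dcm",
                    "q_dcm_nf", "q_hcm_nf", "q_hcm_dcm"):
            assert col in rep.columns

    def test_sorted_by_pooled_abundance(self):
        mat = matrix_from({"low": [1.0] * 9, "high": [500.0] * 9,
                           "mid": [50.0] * 9})
        rep = qt.table_s3_report(qt.group_tests(mat), mat)
        assert rep["miRNA"].tolist() == ["high", "mid", "low"]

    def test_restricted_to_retained_set(self):
        mat = matrix_from({"hsa-miR-195": [100.0] * 9, "keep": [95.0] * 9,
                           "drop": [5.0] * 9})
        retained = qt.mir195_cutoff(mat)
        rep = qt.table_s3_report(qt.group_tests(mat), mat, retained=retained)
        assert set(rep["miRNA"]) == {"hsa-miR-195", "keep"}

    def test_empty_matrix_gives_header_only(self):
        df = pd.DataFrame(columns=LIBS, dtype=float)
        mat = qt.ExpressionMatrix(values=df, groups=GROUPS)
        rep = qt.table_s3_report(qt.group_tests(mat), mat)
        assert len(rep) == 0 and "miRNA" in rep.columns
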