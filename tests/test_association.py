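"""Exact test, odds-ratio flavors, exact CI, BH, capping, plot exports."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given, settings, strategies as st

from recurvar.association import (
    BUILTIN_COVARIATES,
    ContingencyTable,
    CovariateAssociation,
    bh_adjust,
    build_table,
    cap_or_for_plot,
    cmle_or,
    fisher_exact_p,
    sample_or,
)
from recurvar.model import ArrhythmiaCategory, ClinicalRecord, GeneRegistry, Sex

cells = st.integers(min_value=0, max_value=15)


def brute_force_two_sided_p(table: ContingencyTable) -> float:
    """Independent enumeration oracle using scipy's hypergeometric pmf."""
    r1, c1, n = table.row1, table.col1, table.n
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {a: ss.hypergeom.pmf(a, n, c1, r1) for a in range(lo, hi + 1)}
    p_obs = pmf[table.a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisherExact:
    @pytest.mark.parametrize("cells_,expected", [
        ((5, 5, 5, 5), 1.0),
        ((3, 1, 1, 3), 34 / 70),
        ((4, 0, 0, 4), 2 / 70),
    ])
    def test_enumerated_reference_values(self, cells_, expected):
        assert fisher_exact_p(ContingencyTable(*cells_)) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_p(ContingencyTable(0, 0, 3, 4)) == 1.0

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scipy_convention(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        expected = 1.0 if table.degenerate else ss.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_p(table) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_under_row_and_column_swap(self, a, b, c, d):
        p = fisher_exact_p(ContingencyTable(a, b, c, d))
        assert fisher_exact_p(ContingencyTable(d, c, b, a)) == pytest.approx(p, rel=1e-12)


class TestSampleOR:
    @pytest.mark.parametrize("cells_,expected", [
        ((3, 1, 1, 3), 9.0),
        ((5, 0, 5, 10), math.inf),
        ((1, 1, 1, 1), 1.0),
        ((0, 5, 10, 5), 0.0),
    ])
    def test_cross_product(self, cells_, expected):
        assert sample_or(ContingencyTable(*cells_)) == expected

    def test_double_zero_diagonal_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sample_or(ContingencyTable(0, 5, 0, 5))


class TestCMLE:
    def test_independence_table_estimates_unity(self):
        est, lo, hi = cmle_or(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0, abs=1e-6)
        assert lo < 1.0 < hi

    def test_score_equation_grid_oracle(self):
        # independent oracle: E_psi[a] over a psi grid, pick the bracketing root
        table = ContingencyTable(3, 1, 1, 3)
        lo_a, hi_a = 0, 4
        support = np.arange(lo_a, hi_a + 1)
        weights = np.array([math.comb(4, a) * math.comb(4, 4 - a) for a in support])

        def mean_a(psi):
            w = weights * psi ** support
            return float((support * w).sum() / w.sum())

        grid = np.linspace(0.01, 50, 200_000)
        means = np.array([mean_a(p) for p in grid])
        psi_star = float(grid[np.argmin(np.abs(means - 3.0))])
        est, _, _ = cmle_or(table)
        assert est == pytest.approx(psi_star, rel=1e-3)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_transpose_inversion_symmetry(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        if table.degenerate:
            return
        est, lo, hi = cmle_or(table)
        est_t, lo_t, hi_t = cmle_or(table.transposed())
        for x, y in ((est, est_t), (lo, hi_t), (hi, lo_t)):
            if math.isinf(x) or x == 0.0:
                assert y == (0.0 if math.isinf(x) else math.inf)
            else:
                assert x == pytest.approx(1.0 / y, rel=1e-9)

    def test_boundary_table_one_sided_interval(self):
        est, lo, hi = cmle_or(ContingencyTable(5, 0, 5, 10))
        assert est == math.inf and hi == math.inf and lo > 1.0

    def test_matches_r_fisher_test(self):
        tables = [(3, 1, 1, 3), (12, 4, 7, 15), (5, 0, 5, 10), (2, 8, 9, 3)]
        script = ";".join(
            f'f<-fisher.test(matrix(c({a},{b},{c},{d}),2,2,byrow=TRUE));'
            f'cat(sprintf("%.15g",c(f$p.value,f$estimate,f$conf.int)),"\\n")'
            for a, b, c, d in tables)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.strip().splitlines()
        for (a, b, c, d), line in zip(tables, out):
            r_p, r_est, r_lo, r_hi = map(float, line.split())
            table = ContingencyTable(a, b, c, d)
            est, lo, hi = cmle_or(table)
            assert fisher_exact_p(table) == pytest.approx(r_p, rel=1e-9)
            # R solves the score equation with uniroot at ~1e-4 tolerance
            assert est == pytest.approx(r_est, rel=5e-4)
            # R's uniroot endpoints are looser than our brentq tolerance
            assert lo == pytest.approx(r_lo, rel=1e-2)
            if math.isinf(r_hi):
                assert math.isinf(hi)
            else:
                assert hi == pytest.approx(r_hi, rel=1e-2)


class TestBH:
    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.04]) == [0.04]
        assert bh_adjust([0.5, 0.5, 0.5]) == [0.5, 0.5, 0.5]

    def test_step_up_reference(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, rtol=0, atol=1e-15)


class TestCapping:
    @pytest.mark.parametrize("value,expected", [
        (math.inf, 100.0), (0.0, 0.01), (5.2, 5.2),
        (0.005, 0.01), (350.0, 100.0), (0.01, 0.01), (100.0, 100.0),
    ])
    def test_cap_values(self, value, expected):
        assert cap_or_for_plot(value) == expected

    @given(st.floats(min_value=0, max_value=1e6) | st.just(math.inf))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_bounded(self, value):
        capped = cap_or_for_plot(value)
        assert cap_or_for_plot(capped) == capped
        assert 0.01 <= capped <= 100.0


def _cohort(n_early_carriers=5, n_early=10, n_late_carriers=0, n_late=10):
    clinical, carriers = [], set()
    for i in range(n_early):
        pid = f"E{i}"
        clinical.append(ClinicalRecord(pid, Sex.male, 15, ArrhythmiaCategory.atrial, False))
        if i < n_early_carriers:
            carriers.add(pid)
    for i in range(n_late):
        pid = f"L{i}"
        clinical.append(ClinicalRecord(pid, Sex.female, 30, ArrhythmiaCategory.atrial, False))
        if i < n_late_carriers:
            carriers.add(pid)
    return clinical, carriers


class TestBuildTableAndModel:
    def test_counts_land_in_the_right_cells(self):
        clinical, carriers = _cohort()
        table = build_table(carriers, clinical, "very_early_onset")
        assert table.cells() == (5, 0, 5, 10)

    def test_no_carriers(self):
        clinical, _ = _cohort(n_early_carriers=0)
        table = build_table(set(), clinical, "very_early_onset")
        assert (table.a, table.b) == (0, 0) and table.degenerate

    def test_builtin_covariates_dichotomize(self):
        rec = ClinicalRecord("P", Sex.female, 20, ArrhythmiaCategory.ventricular, True)
        assert BUILTIN_COVARIATES["very_early_onset"].rule(rec) == 1
        assert BUILTIN_COVARIATES["female"].rule(rec) == 1
        assert BUILTIN_COVARIATES["cardiomyopathy_positive"].rule(rec) == 1
        rec21 = ClinicalRecord("P", Sex.male, 21, ArrhythmiaCategory.atrial, False)
        assert BUILTIN_COVARIATES["very_early_onset"].rule(rec21) == 0

    def test_model_fit_results_and_exports(self):
        clinical, carriers = _cohort()
        retained = pd.DataFrame({
            "gene": ["G1"] * len(carriers) + ["G2"],
            "patient_id": sorted(carriers) + ["L5"],
            "chrom": "chr1", "pos": 1,
        })
        res = CovariateAssociation(retained, clinical, "very_early_onset").fit()
        frame = res.frame()
        assert set(frame["gene"]) == {"G1", "G2"}
        g1 = frame.set_index("gene").loc["G1"]
        assert (g1["a"], g1["b"], g1["c"], g1["d"]) == (5, 0, 5, 10)
        assert g1["or_sample"] == math.inf
        assert g1["or_capped_for_plot"] == 100.0
        assert "very_early_onset" in res.summary()

        registry = GeneRegistry(genes={"G1": ("chr2", 100), "G2": ("chr1", 200)},
                                chromosome_gene_counts={"chr1": 10, "chr2": 10})
        manhattan = res.manhattan_table(registry=registry)
        assert list(manhattan["gene"]) == ["G2", "G1"]  # chr1 before chr2
        assert manhattan.attrs["significance_line"] == 0.05
        assert manhattan["neg_log10_p"].between(0, 60).all()

        forest = res.forest_table()
        row = forest.set_index("gene").loc["G1"]
        assert row["infinite_or"] and row["or_capped_for_plot"] == 100.0
        assert row["ci_high_capped"] == 100.0

    def test_neg_log10_reference_points(self):
        assert -math.log10(0.05) == pytest.approx(1.3010, abs=5e-5)
        clinical, carriers = _cohort(n_early_carriers=10, n_late_carriers=10)
        retained = pd.DataFrame({"gene": ["G1"] * 20,
                                 "patient_id": sorted(carriers),
                                 "chrom": "chr1", "pos": 1})
        res = CovariateAssociation(retained, clinical, "very_early_onset").fit()
        manhattan = res.manhattan_table()
        assert manhattan["p"].iloc[0] == 1.0 and manhattan["neg_log10_p"].iloc[0] == 0.0

    def test_empty_results_export_headers_only(self):
        retained = pd.DataFrame(columns=["gene", "patient_id"])
        res = CovariateAssociation(retained, [], "female").fit()
        assert res.frame().empty and res.forest_table().empty


class TestCoverage:
    def test_exact_ci_is_conservative_at_nominal_95(self):
        """Planted-OR simulation: empirical coverage of the 95% exact CI."""
        true_or, p0, n = 2.0, 0.3, 200
        odds1 = true_or * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        rng = np.random.default_rng(12)
        covered = 0
        reps = 500
        for _ in range(reps):
            a = rng.binomial(n, p1)
            b = rng.binomial(n, p0)
            table = ContingencyTable(a, n - a, b, n - b)
            _, lo, hi = cmle_or(table)
            covered += lo <= true_or <= hi
        assert covered / reps >= 0.93
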