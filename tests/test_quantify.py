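"""Histogram, double-Gaussian decomposition and HD/CD scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xvlung as xv
from xvlung.core import DegenerateCohortError, NormalizationError, XVError
from xvlung.expansion import ExpansionMap
from xvlung.quantify import (
    DoubleGaussianResults,
    ExpansionHistogram,
    _double_gaussian,
    cd_score,
    cohort_scores,
    expansion_histogram,
    fit_double_gaussian,
)


def flat_map(values):
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return ExpansionMap(values=values, mask=np.ones(values.shape, bool))


def results_with(mu1, mu2, a1=1.0, a2=1.0, s1=0.01, s2=0.01):
    return DoubleGaussianResults(
        model=None,
        params_raw=np.array([a1, mu1, s1, a2, mu2, s2]),
        cov=np.zeros((6, 6)),
        ssr=0.0,
        r_squared=1.0,
    )


class TestHistogram:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        n=st.integers(150, 3000),
        n_bins=st.integers(8, 80),
        scale=st.floats(1e-3, 10.0),
    )
    def test_unit_area_and_bin_invariant_iqr(self, seed, n, n_bins, scale):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0.1, 0.02, n) * scale
        h = expansion_histogram(vals, n_bins=n_bins)
        assert h.area == pytest.approx(1.0, abs=1e-9)
        h2 = expansion_histogram(vals, n_bins=max(8, n_bins // 2))
        assert h.iqr == h2.iqr  # raw-value IQR does not depend on binning

    def test_identical_values_iqr_zero(self):
        h = expansion_histogram(np.full(500, 0.07))
        assert h.iqr == 0.0
        assert h.area == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_iqr_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 0.02
        vals = rng.normal(0.1, sigma, 100_000)
        h = expansion_histogram(vals)
        # IQR of a normal = 2 * Phi^-1(0.75) * sigma = 1.349 sigma
        se = 1.166 * sigma / np.sqrt(vals.size)  # asymptotic SE of the IQR
        assert abs(h.iqr - 1.3490 * sigma) < 3 * se

    def test_small_sample_flagged(self):
        with pytest.warns(UserWarning):
            h = expansion_histogram(np.random.default_rng(0).normal(size=50))
        assert h.flagged

    def test_empty_raises(self):
        with pytest.raises(XVError):
            expansion_histogram(np.array([]))


class TestDoubleGaussianFit:
    def test_noise_free_self_consistency(self):
        edges = np.linspace(0.0, 0.2, 51)
        x = 0.5 * (edges[:-1] + edges[1:])
        true = (3.0, 0.05, 0.011, 8.0, 0.13, 0.015)
        hist = ExpansionHistogram(
            bin_edges=edges, density=_double_gaussian(x, *true), iqr=0.02, n_values=10**5
        )
        fit = fit_double_gaussian(hist)
        for key, val in zip(["a1", "mu1", "sigma1", "a2", "mu2", "sigma2"], true):
            assert fit.params[key] == pytest.approx(val, rel=0.01)
        assert fit.r_squared >= 0.999

    def test_bimodal_sample_recovery(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(0.05, 0.01, 30_000), rng.normal(0.12, 0.01, 70_000)]
        )
        fit = fit_double_gaussian(expansion_histogram(vals, n_bins=50))
        assert fit.params["mu1"] == pytest.approx(0.05, rel=0.05)
        assert fit.params["mu2"] == pytest.approx(0.12, rel=0.05)

    def test_single_gaussian_collapses(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.10, 0.012, 100_000)
        fit = fit_double_gaussian(expansion_histogram(vals, n_bins=50))
        p = fit.params
        sep = (p["mu2"] - p["mu1"]) / p["mu2"]
        amp_ratio = min(p["a1"], p["a2"]) / max(p["a1"], p["a2"])
        assert sep <= 0.02 or amp_ratio <= 0.01 or fit.unimodal
        assert fit.cd == 0.0

    def test_canonical_ordering(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0.12, 0.01, 50_000), rng.normal(0.05, 0.01, 50_000)])
        fit = fit_double_gaussian(expansion_histogram(vals))
        assert fit.params["mu1"] <= fit.params["mu2"]
        assert fit.params["sigma1"] > 0 and fit.params["sigma2"] > 0
        assert fit.r_squared <= 1.0

    def test_too_few_bins(self):
        h = expansion_histogram(np.random.default_rng(0).normal(size=500), n_bins=5)
        with pytest.raises(XVError):
            fit_double_gaussian(h)

    def test_summary_smoke(self):
        rng = np.random.default_rng(7)
        fit = fit_double_gaussian(expansion_histogram(rng.normal(0.1, 0.02, 5000)))
        text = fit.summary()
        assert "R^2" in text and "mu2" in text


class TestCDScore:
    def test_identical_modes_zero(self):
        assert cd_score(results_with(0.08, 0.08)) == 0.0

    def test_direct_formula(self):
        assert cd_score(results_with(0.05, 0.10)) == pytest.approx(0.5)

    def test_most_clustered_reported_magnitude(self):
        # a strongly clustered profile: modes 0.033/0.05 give CD = 0.34
        assert cd_score(results_with(0.033, 0.05)) == pytest.approx(0.34)

    def test_nonpositive_mu2_rejected(self):
        with pytest.raises(XVError):
            cd_score(results_with(-0.02, 0.0))

    def test_negligible_minor_component_is_unimodal(self):
        fit = results_with(0.02, 0.10, a1=0.001, a2=1.0)
        assert fit.unimodal
        assert cd_score(fit) == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(mu2=st.floats(0.05, 0.5), frac=st.floats(0.01, 0.99))
    def test_bounded_and_monotone(self, mu2, frac):
        mu1 = frac * mu2
        cd = cd_score(results_with(mu1, mu2))
        assert 0 <= cd < 1
        cd_lower = cd_score(results_with(0.5 * mu1, mu2))
        assert cd_lower >= cd  # decreasing mu1 increases CD


class TestCohortScores:
    def exact_iqr_map(self, iqr, center=0.1, n=4001):
        # evenly spaced values have IQR exactly half the range
        return flat_map(np.linspace(center - iqr, center + iqr, n))

    def test_hd_definition_and_littermate_mean(self):
        records = [
            ("L1", "littermate", self.exact_iqr_map(0.008)),
            ("L2", "littermate", self.exact_iqr_map(0.010)),
            ("L3", "littermate", self.exact_iqr_map(0.012)),
            ("D1", "disease", self.exact_iqr_map(0.0178)),
        ]
        ct = cohort_scores(records)
        assert ct.iqr_L == pytest.approx(0.010, rel=1e-6)
        d1 = ct.table.set_index("id").loc["D1", "hd"]
        assert d1 == pytest.approx(1.78, rel=1e-6)
        litter = ct.table[ct.table.group == "littermate"]["hd"]
        assert litter.mean() == pytest.approx(1.0, abs=1e-12)

    def test_animal_matching_reference_has_unit_hd(self):
        records = [("L1", "littermate", self.exact_iqr_map(0.01))]
        ct = cohort_scores(records)
        assert ct.table["hd"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_of_hd(self):
        rng = np.random.default_rng(0)
        base = [rng.normal(0.1, s, 3000) for s in (0.01, 0.015, 0.02, 0.03)]
        groups = ["littermate", "littermate", "littermate", "disease"]
        rec1 = [(f"A{i}", g, flat_map(v)) for i, (g, v) in enumerate(zip(groups, base))]
        rec2 = [(f"A{i}", g, flat_map(5.0 * v)) for i, (g, v) in enumerate(zip(groups, base))]
        hd1 = cohort_scores(rec1).table["hd"].to_numpy()
        hd2 = cohort_scores(rec2).table["hd"].to_numpy()
        assert np.allclose(hd1, hd2, rtol=1e-9)

    def test_no_littermates_raises(self):
        with pytest.raises(NormalizationError):
            cohort_scores([("D1", "disease", self.exact_iqr_map(0.01))])

    def test_degenerate_cohort_raises(self):
        records = [("L1", "littermate", flat_map(np.full(500, 0.1)))]
        with pytest.raises(DegenerateCohortError):
            cohort_scores(records)

    def test_heart_blur_suppresses_cd(self):
        rng = np.random.default_rng(1)
        records = [
            ("L1", "littermate", flat_map(rng.normal(0.1, 0.01, 3000))),
            ("D1", "disease", flat_map(rng.normal(0.1, 0.02, 3000))),
        ]
        ct = cohort_scores(records, extras={"D1": {"heart_blur_flag": True}})
        row = ct.table.set_index("id").loc["D1"]
        assert bool(row["heart_blur_flag"])
        assert np.isnan(row["cd"])
        assert np.isfinite(row["hd"])
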