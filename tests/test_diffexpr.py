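"""TMM normalisation, dispersion, NB GLMs, contrasts, BH and summaries."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressmir.diffexpr import (
    bh_fdr,
    de_sets,
    design_matrix,
    direction_by_time,
    estimate_dispersion,
    fit_nb_glm,
    heatmap_matrix,
    tmm_factors,
    venn_counts,
    NormFactors,
)
from stressmir.diffexpr import test_contrasts as de_contrasts
from stressmir.simulate import SimTruth, full_design, simulate_counts

DESIGN = full_design()


def tmm_reference(y, lib_sizes, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step TMM reimplementation (plain loops)."""
    y = np.asarray(y, dtype=float)
    n_libs = y.shape[1]
    f75 = []
    for k in range(n_libs):
        f75.append(np.percentile(y[:, k] / lib_sizes[k], 75))
    ref = min(range(n_libs), key=lambda k: abs(f75[k] - sum(f75) / n_libs))
    factors = []
    for k in range(n_libs):
        if k == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(y.shape[0]):
            o, r = y[g, k], y[g, ref]
            if o > 0 and r > 0:
                m_vals.append(np.log2((o / lib_sizes[k]) / (r / lib_sizes[ref])))
                a_vals.append(0.5 * np.log2((o / lib_sizes[k]) * (r / lib_sizes[ref])))
                w_vals.append(
                    (lib_sizes[k] - o) / (lib_sizes[k] * o)
                    + (lib_sizes[ref] - r) / (lib_sizes[ref] * r)
                )
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        if len(m_vals) == 0 or np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = stats.rankdata(m_vals), stats.rankdata(a_vals)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2 ** (np.sum(m_vals[keep] / w_vals[keep]) / np.sum(1 / w_vals[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self, rng):
        v = rng.poisson(60, 300)
        counts = pd.DataFrame({f"l{i}": v for i in range(4)})
        assert tmm_factors(counts).tmm_factor == pytest.approx(np.ones(4))

    def test_tagwise_doubled_library_closed_form(self):
        """Constant M = 1 at equal stated library sizes: factors {1/sqrt2, sqrt2}."""
        counts = pd.DataFrame({"a": [10, 20, 30, 40, 100], "b": [20, 40, 60, 80, 200]})
        f = tmm_factors(counts, lib_sizes=[1000, 1000]).tmm_factor
        assert f == pytest.approx([2 ** -0.5, 2 ** 0.5], abs=1e-6)

    def test_matches_independent_reimplementation(self, rng):
        for _ in range(5):
            y = rng.negative_binomial(5, 0.05, size=(200, 6))
            counts = pd.DataFrame(y, columns=[f"l{i}" for i in range(6)])
            mine = tmm_factors(counts).tmm_factor
            ref = tmm_reference(y, y.sum(axis=0))
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_matches_edger(self, rng, tmp_path):
        """Bioconductor edgeR as an independent oracle on one matrix."""
        y = rng.negative_binomial(4, 0.03, size=(150, 5))
        path = tmp_path / "counts.tsv"
        np.savetxt(path, y, fmt="%d", delimiter="\t")
        r = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(edgeR)); '
                f'y <- as.matrix(read.table("{path}")); '
                f'cat(sprintf("%.10f ", calcNormFactors(y, method="TMM")))',
            ],
            capture_output=True, text=True, timeout=120,
        )
        assert r.returncode == 0, r.stderr
        edger = np.array([float(x) for x in r.stdout.split()])
        mine = tmm_factors(pd.DataFrame(y)).tmm_factor
        assert mine == pytest.approx(edger, abs=1e-6)

    def test_scale_invariance(self, rng):
        y = rng.negative_binomial(5, 0.05, size=(300, 4)) + 1
        counts = pd.DataFrame(y)
        scaled = counts.copy()
        scaled[0] = scaled[0] * 4
        f0 = tmm_factors(counts).tmm_factor
        f1 = tmm_factors(scaled).tmm_factor
        # library sizes absorb the scaling: factors change only via trimming noise
        assert f1 == pytest.approx(f0, rel=0.02)


def _nb_counts(mu, phi, rng, n=None):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=n)


class TestDispersion:
    def test_poisson_data_drives_common_to_zero_boundary(self, rng):
        mu = rng.lognormal(np.log(100), 1.0, 400)
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], (400, 72)), columns=[d.library_id for d in DESIGN]
        )
        common, _ = estimate_dispersion(counts, DESIGN)
        assert common <= 1e-3

    def test_prior_weight_infinity_collapses_to_common(self, rng):
        mu = rng.lognormal(np.log(100), 0.8, 300)
        counts = pd.DataFrame(
            _nb_counts(mu[:, None], 0.1, rng, (300, 72)),
            columns=[d.library_id for d in DESIGN],
        )
        common, tagwise = estimate_dispersion(counts, DESIGN, prior_df=1e9)
        assert tagwise == pytest.approx(np.full(300, common), rel=1e-4)

    def test_common_recovered_at_known_truth(self, rng):
        """Monte-Carlo calibration at phi = 0.1 (fixed seed)."""
        mu = rng.lognormal(np.log(200), 1.0, 2000)
        counts = pd.DataFrame(
            _nb_counts(mu[:, None], 0.1, rng, (2000, 72)),
            columns=[d.library_id for d in DESIGN],
        )
        common, _ = estimate_dispersion(counts, DESIGN)
        assert common == pytest.approx(0.1, abs=0.02)


class TestGlm:
    def test_constant_counts_zero_nonintercept_coefficients(self):
        counts = pd.DataFrame(
            np.full((3, 72), 50), columns=[d.library_id for d in DESIGN]
        )
        fit = fit_nb_glm(counts, DESIGN, offsets=np.zeros(72), dispersion=0.1)
        assert fit.beta[:, 1:] == pytest.approx(np.zeros((3, 23)), abs=1e-6)
        assert fit.converged.all()

    def test_poisson_two_group_closed_form(self, rng):
        """With a saturated 2-level design the MLE is the log mean ratio."""
        half = DESIGN[:36]
        y = np.concatenate([rng.poisson(40, 18), rng.poisson(80, 18)])
        # build a 2-column design by hand
        X = np.column_stack([np.ones(36), np.r_[np.zeros(18), np.ones(18)]])
        counts = pd.DataFrame(y[None, :], columns=[d.library_id for d in half])
        fit = fit_nb_glm(
            counts, half, offsets=np.zeros(36), dispersion=1e-8,
            X=X, columns=["intercept", "grp"],
        )
        expect = np.log(y[18:].mean() / y[:18].mean())
        assert fit.beta[0, 1] == pytest.approx(expect, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        """statsmodels NB GLM as an independent oracle on a few tags."""
        import statsmodels.api as sm

        X, cols = design_matrix(DESIGN)
        mu = 200 * np.ones(72)
        for seed in range(3):
            y = _nb_counts(mu, 0.15, np.random.default_rng(seed))
            counts = pd.DataFrame(y[None, :], columns=[d.library_id for d in DESIGN])
            fit = fit_nb_glm(counts, DESIGN, offsets=np.zeros(72), dispersion=0.15)
            ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.15)).fit()
            assert fit.beta[0] == pytest.approx(ref.params, abs=1e-4)

    def test_planted_coefficient_recovered(self, rng):
        base = {f"t{i}": 1000.0 for i in range(60)}
        eff = {f"t{i}": {("heat", 0): -2.0} for i in range(60)}
        truth = SimTruth([], eff, base, 0.05, 77)
        counts = simulate_counts(DESIGN, truth, np.random.default_rng(77))
        fit = fit_nb_glm(counts, DESIGN, offsets=np.zeros(72), dispersion=0.05)
        X, cols = design_matrix(DESIGN)
        heat = cols.index("trt_heat")
        mean_beta = fit.beta[:, heat].mean() / np.log(2)
        assert mean_beta == pytest.approx(-2.0, abs=0.15)


class TestContrasts:
    def test_bh_closed_form(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_monotone_in_rank(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p)

    def test_heat_only_effects_yield_venn_asymmetry(self, rng):
        """Planted heat effects produce a heat-dominated DE partition."""
        base = {f"t{i:03d}": float(500 * rng.lognormal(0, 0.4)) for i in range(300)}
        eff = {f"t{i:03d}": {("heat", 0): -2.0, ("heat", 1): -2.0} for i in range(40)}
        truth = SimTruth([], eff, base, 0.08, 55)
        counts = simulate_counts(DESIGN, truth, np.random.default_rng(55))
        res = de_contrasts(counts, DESIGN)
        sets = de_sets(res)
        planted = {f"t{i:03d}" for i in range(40)}
        assert len(sets["heat"] & planted) >= 32  # >= 80% power
        assert len(sets["light"]) <= 3 and len(sets["uv"]) <= 3
        venn = venn_counts(sets)
        assert venn["heat_only"] > 10 * max(venn["light_only"], venn["uv_only"], 1) / 2
        # direction accounting: planted downregulation dominates the early days
        tab = direction_by_time(res, "heat").set_index("time_dat")
        assert tab.loc[0, "down"] > tab.loc[0, "up"]
        assert tab.loc[1, "down"] > tab.loc[1, "up"]
        # per-time significance: effects confined to days 0-1, none at day 7
        strict = direction_by_time(res, "heat", require_time_significance=True)
        strict = strict.set_index("time_dat")
        assert strict.loc[0, "down"] > strict.loc[0, "up"]
        assert strict.loc[7, "down"] + strict.loc[7, "up"] <= 5

    def test_venn_closed_forms(self):
        sets = {"heat": set(range(79)), "light": {100, 101}, "uv": {200}}
        v = venn_counts(sets)
        assert (v["heat_only"], v["light_only"], v["uv_only"]) == (79, 2, 1)
        assert sum(v.values()) == 82
        same = {"heat": {1, 2}, "light": {1, 2}, "uv": {1, 2}}
        assert venn_counts(same)["heat_light_uv"] == 2

    def test_venn_matches_brute_force(self, rng):
        universe = list(range(50))
        sets = {
            t: set(rng.choice(universe, size=20, replace=False)) for t in ("heat", "light", "uv")
        }
        v = venn_counts(sets)
        regions = {k: 0 for k in v}
        for x in universe:
            inh, inl, inu = (x in sets["heat"], x in sets["light"], x in sets["uv"])
            key = {
                (1, 0, 0): "heat_only", (0, 1, 0): "light_only", (0, 0, 1): "uv_only",
                (1, 1, 0): "heat_light", (1, 0, 1): "heat_uv", (0, 1, 1): "light_uv",
                (1, 1, 1): "heat_light_uv",
            }.get((inh, inl, inu))
            if key:
                regions[key] += 1
        assert v == regions


class TestHeatmap:
    def test_zero_count_unit_effective_size_gives_zero(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [1, 2]}, index=["x", "y"])
        norm = NormFactors(tmm_factor=np.ones(2), lib_size=np.ones(2))
        mat, _, _ = heatmap_matrix(counts, norm, ["x", "y"], pseudocount=1.0)
        assert mat.loc["x", "a"] == pytest.approx(0.0)

    def test_duplicated_libraries_cluster_adjacently(self, rng):
        y = rng.poisson(30, size=(20, 3))
        counts = pd.DataFrame(
            np.column_stack([y[:, 0], y[:, 1], y[:, 0], y[:, 2]]),
            columns=["a", "b", "a2", "c"],
            index=[f"t{i}" for i in range(20)],
        )
        norm = NormFactors(tmm_factor=np.ones(4), lib_size=np.ones(4))
        _, _, col_order = heatmap_matrix(counts, norm, list(counts.index))
        pos = {counts.columns[i]: r for r, i in enumerate(col_order)}
        assert abs(pos["a"] - pos["a2"]) == 1

    def test_linkage_heights_match_recomputation(self, rng):
        from scipy.cluster.hierarchy import leaves_list, linkage

        y = rng.poisson(50, size=(6, 4))
        counts = pd.DataFrame(y, index=[f"t{i}" for i in range(6)])
        norm = NormFactors(tmm_factor=np.ones(4), lib_size=np.full(4, 100.0))
        mat, row_order, _ = heatmap_matrix(counts, norm, list(counts.index))
        expect = list(leaves_list(linkage(mat.to_numpy(), "average", "euclidean")))
        assert row_order == expect

    def test_empty_de_set_rejected(self):
        counts = pd.DataFrame({"a": [1]}, index=["x"])
        norm = NormFactors(tmm_factor=np.ones(1), lib_size=np.ones(1))
        with pytest.raises(ValueError):
            heatmap_matrix(counts, norm, [])
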