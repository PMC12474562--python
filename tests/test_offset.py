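"""Climate PCA, loading gate, decorrelation, gradient forest, offsets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salrun import sim
from salrun.offset import (
    TurnoverModel,
    bonferroni_alpha,
    climate_pca,
    compare_r2_distributions,
    correlate_loadings,
    decorrelate_predictors,
    environmental_offset,
    fit_gradient_forest,
    gea_rda,
    genomic_offset,
    multi_run_protocol,
)


def climate_frame(n_sites=8, n_vars=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_sites, n_vars)),
        index=[f"S{i}" for i in range(n_sites)],
        columns=[f"V{j}" for j in range(n_vars)],
    )


class TestClimatePCA:
    def test_future_equals_present_identical_scores(self):
        present = climate_frame()
        pca = climate_pca(present)
        pd.testing.assert_frame_equal(pca.transform(present), pca.transform(present.copy()))

    def test_two_sites_degenerate(self):
        with pytest.raises(ValueError):
            climate_pca(climate_frame(n_sites=2))

    def test_constant_variable_dropped(self, caplog):
        present = climate_frame()
        present["CONST"] = 1.0
        with caplog.at_level("WARNING"):
            pca = climate_pca(present)
        assert "CONST" not in pca.variables

    def test_matches_dense_eigen_oracle(self):
        present = climate_frame(10, 6, seed=3)
        pca = climate_pca(present, n_pcs=4)
        z = ((present - present.mean()) / present.std(ddof=1)).to_numpy()
        evals = np.linalg.eigvalsh(z.T @ z)[::-1]
        np.testing.assert_allclose(pca.explained_var, evals[:4] / evals.sum(), atol=1e-10)


class TestGEA:
    def test_planted_climate_loci_rank_top(self, small_sim):
        cfg, g, truth = small_sim["cfg"], small_sim["g"], small_sim["truth"]
        clim = sim.simulate_climate(cfg)
        present = sim.climate_wide(clim, "present")
        pca = climate_pca(present, 3)
        scores = pca.transform(present)
        site_pcs = scores.loc[g.pop_labels].to_numpy()
        res = gea_rda(g, site_pcs, top=0.05)
        planted = set().union(*truth.trait_loci.values())
        hits = len(set(res.candidates.tolist()) & planted)
        null_rate = len(planted) / cfg.n_snps
        assert hits / len(res.candidates) > 3 * null_rate

    def test_no_signal_low_constrained_variance(self):
        rng = np.random.default_rng(0)
        from conftest import toy_genotypes

        x = rng.binomial(2, 0.5, size=(40, 30)).astype(float)
        pcs = rng.normal(size=(40, 3))
        res = gea_rda(toy_genotypes(x), pcs)
        assert res.constrained_var < 0.25


class TestCorrelationGate:
    def test_identical_vectors_pass(self):
        v = pd.Series(np.random.default_rng(0).normal(size=50))
        gate = correlate_loadings(v, v)
        assert gate.r == pytest.approx(1.0)
        assert gate.passed

    def test_bonferroni_constant(self):
        assert bonferroni_alpha(3) == 0.0167

    def test_no_shared_loci_errors(self):
        a = pd.Series([1.0, 2.0, 3.0], index=[0, 1, 2])
        b = pd.Series([1.0, 2.0, 3.0], index=[10, 11, 12])
        with pytest.raises(ValueError):
            correlate_loadings(a, b)

    def test_null_pass_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        passes = 0
        n_rep = 400
        for _ in range(n_rep):
            a = pd.Series(rng.normal(size=100))
            b = pd.Series(rng.normal(size=100))
            passes += correlate_loadings(a, b).passed
        assert passes / n_rep <= 0.035  # alpha 0.0167 plus 3 binomial sd

    def test_spearman_used_for_non_normal(self):
        rng = np.random.default_rng(2)
        a = pd.Series(np.exp(rng.normal(size=80) * 3))  # heavy-tailed
        b = pd.Series(a.to_numpy() + rng.normal(size=80) * 1e-6)
        gate = correlate_loadings(a, b)
        assert gate.method == "spearman"


class TestDecorrelate:
    def test_duplicate_variable_dropped(self):
        present = climate_frame(10, 3, seed=4)
        present["V0_copy"] = present["V0"]
        imp = pd.Series({"V0": 1.0, "V1": 0.5, "V2": 0.4, "V0_copy": 0.2})
        keep = decorrelate_predictors(present, imp, 0.7)
        assert "V0" in keep and "V0_copy" not in keep

    def test_all_below_threshold_unchanged(self):
        present = climate_frame(50, 4, seed=5)
        imp = pd.Series(1.0, index=present.columns)
        assert decorrelate_predictors(present, imp, 0.7) == list(present.columns)

    def test_chain_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        present = pd.DataFrame(
            {
                "A": base,
                "B": base + rng.normal(0, 0.3, 30),
                "C": base + rng.normal(0, 0.35, 30),
            },
            index=[f"S{i}" for i in range(30)],
        )
        imp = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        keep = decorrelate_predictors(present, imp, 0.7)
        # oracle: greedy removal by max |r| pair, lower importance dropped
        live = ["A", "B", "C"]
        while True:
            corr = present[live].corr().abs()
            worst, pair = 0.7, None
            for i, a in enumerate(live):
                for b in live[i + 1 :]:
                    if corr.loc[a, b] > worst:
                        worst, pair = corr.loc[a, b], (a, b)
            if pair is None:
                break
            live.remove(pair[0] if imp[pair[0]] < imp[pair[1]] else pair[1])
        assert keep == live


def step_freqs(n_sites=10, seed=0):
    """One locus that is a step function of V0, plus noise predictors."""
    rng = np.random.default_rng(seed)
    present = pd.DataFrame(
        {
            "V0": np.linspace(-1, 1, n_sites),
            "V1": rng.normal(size=n_sites),
            "V2": rng.normal(size=n_sites),
        },
        index=[f"S{i}" for i in range(n_sites)],
    )
    freq = np.where(present["V0"] > 0.1, 0.8, 0.2)
    freqs = pd.DataFrame([freq], index=["locus1"], columns=present.index)
    return freqs, present


class TestGradientForest:
    def test_step_predictor_takes_importance(self):
        freqs, present = step_freqs()
        m = fit_gradient_forest(freqs, present, n_trees=100, seed=0)
        assert m.predictor_importance.idxmax() == "V0"
        assert m.predictor_importance["V0"] > 0.8
        # turnover jumps near the step location
        bp, cum = m.functions["V0"]
        f_lo = m.evaluate("V0", -0.5)[0]
        f_hi = m.evaluate("V0", 0.5)[0]
        assert f_hi - f_lo > 0.6

    def test_pure_noise_locus_not_retained(self):
        rng = np.random.default_rng(1)
        present = climate_frame(10, 3, seed=2)
        freqs = pd.DataFrame(
            [rng.uniform(0.2, 0.8, 10)], index=["noise"], columns=present.index
        )
        m = fit_gradient_forest(freqs, present, n_trees=100, seed=0)
        assert m.retained_loci == []

    def test_permutation_destroys_r2(self):
        freqs, present = step_freqs()
        base = fit_gradient_forest(freqs, present, n_trees=100, seed=0).r2["locus1"]
        rng = np.random.default_rng(2)
        worse = 0
        n_perm = 30
        for k in range(n_perm):
            perm = freqs.iloc[:, rng.permutation(freqs.shape[1])]
            perm.columns = freqs.columns
            r2p = fit_gradient_forest(perm, present, n_trees=50, seed=k).r2["locus1"]
            worse += r2p < base
        assert worse / n_perm >= 0.9

    def test_turnover_invariants(self, small_sim):
        cfg, g, truth = small_sim["cfg"], small_sim["g"], small_sim["truth"]
        clim = sim.simulate_climate(cfg)
        present = sim.climate_wide(clim, "present").iloc[:, :6]
        loci = truth.trait_loci["late"][:8]
        freqs = g.pop_freqs().iloc[:, loci].T
        freqs.index = [f"L{j}" for j in loci]
        m = fit_gradient_forest(freqs, present, n_trees=60, seed=0)
        total = 0.0
        for v, (bp, cum) in m.functions.items():
            if bp.size:
                assert (np.diff(cum) >= -1e-12).all()  # non-decreasing
                assert cum[-1] == pytest.approx(m.predictor_importance[v], abs=1e-12)
                total += cum[-1]
        if any(bp.size for bp, _ in m.functions.values()):
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_too_few_sites_errors(self):
        freqs, present = step_freqs(n_sites=3)
        with pytest.raises(ValueError):
            fit_gradient_forest(freqs, present.iloc[:3], n_trees=10, seed=0)


def manual_model(functions):
    imp = pd.Series({v: (cum[-1] if len(cum) else 0.0) for v, (bp, cum) in functions.items()})
    return TurnoverModel(
        functions={v: (np.asarray(bp, float), np.asarray(cum, float)) for v, (bp, cum) in functions.items()},
        r2=pd.Series(dtype=float),
        retained_loci=[],
        predictor_importance=imp,
        n_trees=0,
    )


class TestGenomicOffset:
    def test_zero_when_future_equals_present(self):
        freqs, present = step_freqs()
        m = fit_gradient_forest(freqs, present, n_trees=50, seed=0)
        off = genomic_offset(m, present, present.copy())
        assert (off == 0).all()

    def test_zero_importance_predictor_ignored(self):
        m = manual_model({"A": ([0.0, 1.0], [0.3, 0.6]), "B": ([], [])})
        present = pd.DataFrame({"A": [0.5, 0.5], "B": [0.0, 0.0]}, index=["S1", "S2"])
        future = present.copy()
        future["B"] += 10.0
        off = genomic_offset(m, present, future)
        assert (off == 0).all()

    def test_linear_turnover_doubles_with_displacement(self):
        # dense uniform breakpoints -> F approximately linear with slope 0.1/unit
        bp = np.linspace(0, 10, 1001)
        cum = np.linspace(0.001, 1.0, 1001)
        m = manual_model({"A": (bp, cum)})
        present = pd.DataFrame({"A": [2.0]}, index=["S"])
        f1 = present + 1.0
        f2 = present + 2.0
        o1 = genomic_offset(m, present, f1)["S"]
        o2 = genomic_offset(m, present, f2)["S"]
        assert o2 == pytest.approx(2 * o1, rel=1e-2)

    def test_metric_properties(self):
        rng = np.random.default_rng(3)
        funcs = {}
        for v in ("A", "B"):
            bp = np.sort(rng.uniform(-2, 2, 15))
            steps = rng.uniform(0, 1, 15)
            funcs[v] = (bp, np.cumsum(steps / steps.sum() / 2))
        m = manual_model(funcs)
        states = [
            pd.DataFrame({"A": [rng.uniform(-2, 2)], "B": [rng.uniform(-2, 2)]}, index=["S"])
            for _ in range(3)
        ]
        d01 = genomic_offset(m, states[0], states[1])["S"]
        d10 = genomic_offset(m, states[1], states[0])["S"]
        d02 = genomic_offset(m, states[0], states[2])["S"]
        d12 = genomic_offset(m, states[1], states[2])["S"]
        assert d01 == pytest.approx(d10, abs=1e-12)  # symmetry
        assert d02 <= d01 + d12 + 1e-12  # triangle inequality


class TestMultiRun:
    def test_stable_signal_three_runs(self):
        freqs, present = step_freqs()
        future = present + 0.5
        res = multi_run_protocol(freqs, present, future, n_trees=80, seed=0)
        assert res.n_runs == 3
        assert res.most_important_variable == "V0"

    def test_tied_predictors_trigger_ten_runs(self):
        rng = np.random.default_rng(4)
        n = 10
        present = pd.DataFrame(
            {"A": rng.normal(size=n), "B": rng.normal(size=n), "C": rng.normal(size=n)},
            index=[f"S{i}" for i in range(n)],
        )
        # pure-noise response: importance ranking is unstable across seeds
        freqs = pd.DataFrame(
            rng.uniform(0.3, 0.7, size=(4, n)),
            index=[f"L{k}" for k in range(4)],
            columns=present.index,
        )
        res = multi_run_protocol(freqs, present, present + 0.1, n_trees=20, seed=1)
        assert res.n_runs in (3, 10)  # usually 10; 3 only if ranking happens to agree


class TestEnvironmentalOffset:
    def test_zero_when_future_equals_present(self):
        present = climate_frame()
        off = environmental_offset(present, present.copy())
        assert np.allclose(off, 0.0)

    def test_single_variable_shift_closed_form(self):
        present = climate_frame(12, 4, seed=7)
        delta = 1.7
        future = present.copy()
        future["V2"] += delta
        pca = climate_pca(present, n_pcs=2)
        j = pca.variables.index("V2")
        expected = delta / pca.sd["V2"] * np.linalg.norm(pca.components[:, j])
        off = environmental_offset(present, future)
        np.testing.assert_allclose(off, expected, atol=1e-8)

    def test_monotone_in_displacement(self):
        present = climate_frame()
        offs = []
        for d in (0.5, 1.0, 2.0):
            future = present + d
            offs.append(environmental_offset(present, future).mean())
        assert offs[0] < offs[1] < offs[2]


class TestWilcoxon:
    def test_exact_enumeration(self):
        assert compare_r2_distributions([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert compare_r2_distributions([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_large_shifted_normals(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 300)
        b = rng.normal(2, 1, 300)
        assert compare_r2_distributions(a, b) < 1e-6

    def test_matches_scipy_on_large_samples(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=40), rng.normal(0.3, 1, 50)
        ours = compare_r2_distributions(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)
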