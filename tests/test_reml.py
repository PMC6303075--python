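"""Design construction and unconstrained REML against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sexdiallel import DiallelDataset, SimulationConfig, generate_diallel
from sexdiallel.reml import (ModelSpec, RemlOptions, build_design,
                             conditional_residuals, extract_blups, fit_reml)

_LOG2PI = np.log(2 * np.pi)


def dense_reml_loglik(y, X, V):
    """Independent dense REML log-likelihood (no Woodbury tricks)."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                   + r @ Vi @ r + (n - p) * _LOG2PI)


@pytest.fixture(scope="module")
def tiny_additive_ds():
    """4 strains, additive-only genetic signal, one sex, no blocks."""
    rng = np.random.default_rng(123)
    effects = rng.normal(0.0, 0.4, size=4)
    rows = []
    for dam in range(1, 5):
        for sire in range(1, 5):
            for _ in range(4):
                latent = 3.5 + effects[dam - 1] + effects[sire - 1] \
                    + rng.normal(0, 0.3)
                rows.append((dam, sire, "F", 1,
                             int(max(0, round(np.exp(latent))))))
    return DiallelDataset(pd.DataFrame(
        rows, columns=["dam", "sire", "sex", "block", "fitness"]),
        n_strains=4)


class TestBuildDesign:
    def test_hand_written_incidence_4_strains(self, balanced4_ds):
        spec = ModelSpec.full_sexed()
        d = build_design(balanced4_ds, spec)
        df = d.ds.df
        dam = df["dam"].to_numpy()
        sire = df["sire"].to_numpy()
        sex = np.where(df["sex"].to_numpy() == "F", 1.0, -1.0)
        strains = np.arange(1, 5)
        # hand-constructed oracles for the strain-level terms
        A = (dam[:, None] == strains) * 1.0 + (sire[:, None] == strains)
        C = (dam[:, None] == strains) * 1.0 - (sire[:, None] == strains)
        B2 = (((dam[:, None] == strains) | (sire[:, None] == strains))
              & (dam != sire)[:, None]) * 1.0
        assert np.array_equal(d.Z["a"], A)
        assert np.array_equal(d.Z["c"], C)
        assert np.array_equal(d.Z["b2"], B2)
        assert np.array_equal(d.Z["S.a"], A * sex[:, None])
        # self rows: a entry 2 for the strain, c entry 0, b2 entry 0
        self_rows = dam == sire
        assert (d.Z["a"][self_rows].max(axis=1) == 2).all()
        assert (d.Z["c"][self_rows] == 0).all()
        assert (d.Z["b2"][self_rows] == 0).all()
        # pair terms: raw indicators projected orthogonal to strain margins
        pairs = d.labels["b3"]
        raw = np.zeros((len(df), len(pairs)))
        for r, (i, j) in enumerate(zip(dam, sire)):
            if i != j:
                raw[r, pairs.index((min(i, j), max(i, j)))] = 1.0
        Q = np.zeros((len(pairs), 5))
        for k, (i, j) in enumerate(pairs):
            Q[k, i - 1] = Q[k, j - 1] = 1.0
        Q[:, 4] = 1.0
        expected = raw @ (np.eye(len(pairs)) - Q @ np.linalg.pinv(Q))
        assert np.allclose(d.Z["b3"], expected, atol=1e-12)
        # response is log(fitness + offset)
        assert np.allclose(d.y, np.log(df["fitness"].to_numpy(float) + 1.0))

    def test_pair_level_counts_16_strains(self):
        cfg = SimulationConfig(seed=2, replicates=1, missingness=0.0)
        ds, _ = generate_diallel(cfg)
        d = build_design(ds, ModelSpec.full_sexed())
        assert d.Z["b3"].shape[1] == 120
        assert d.Z["d"].shape[1] == 120
        # the d incidence distinguishes the 240 ordered outcross pairs
        outcross = (ds.df["dam"] != ds.df["sire"]).to_numpy()
        rows = d.Z["d"][outcross]
        assert len(np.unique(np.round(rows, 9), axis=0)) == 240

    def test_sex_subset_filters_and_forbids_sexed_terms(self, balanced4_ds):
        d = build_design(balanced4_ds, ModelSpec.sex_specific("M"))
        assert (d.ds.df["sex"] == "M").all()
        with pytest.raises(ValueError, match="sexed"):
            ModelSpec(fixed=("mu", "S"), random=("a",), subset="male")

    def test_empty_random_term_rejected(self, balanced4_ds):
        selfs_only = balanced4_ds.df[
            balanced4_ds.df["dam"] == balanced4_ds.df["sire"]]
        ds = DiallelDataset(selfs_only, n_strains=4)
        with pytest.raises(ValueError, match="non-empty"):
            build_design(ds, ModelSpec(fixed=("mu",), random=("b3",)))


class TestFitRemlOracles:
    def test_optimum_beats_brute_force_grid(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        d = build_design(tiny_additive_ds, spec)
        fit = fit_reml(d)
        assert fit.converged
        grid_best = -np.inf
        for s_a in np.linspace(0.005, 0.6, 50):
            for s_e in np.linspace(0.005, 0.6, 50):
                V = s_a * d.Z["a"] @ d.Z["a"].T + s_e * np.eye(len(d.y))
                grid_best = max(grid_best,
                                dense_reml_loglik(d.y, d.X, V))
        assert fit.loglik >= grid_best - 1e-6

    def test_blups_match_henderson_equations(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        d = build_design(tiny_additive_ds, spec)
        fit = fit_reml(d)
        s_a, s_e = fit.varcomp["a"], fit.sigma2_eps
        assert s_a > 0
        X, Z, y = d.X, d.Z["a"], d.y
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + (s_e / s_a) * np.eye(4)])
        sol = np.linalg.solve(np.vstack([top, bot]),
                              np.concatenate([X.T @ y, Z.T @ y]))
        u_oracle = sol[X.shape[1]:]
        blup = extract_blups(fit, "a")
        assert np.allclose(blup.values, u_oracle, atol=1e-8)
        assert blup.labels == [1, 2, 3, 4]

    def test_dense_loglik_agrees_with_reduced_form(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        d = build_design(tiny_additive_ds, spec)
        fit = fit_reml(d)
        V = (fit.varcomp["a"] * d.Z["a"] @ d.Z["a"].T
             + fit.sigma2_eps * np.eye(len(d.y)))
        assert fit.loglik == pytest.approx(
            dense_reml_loglik(d.y, d.X, V), abs=1e-8)

    def test_residual_variance_positive(self, small_sim):
        ds, _ = small_sim
        fit = fit_reml(build_design(ds, ModelSpec.residualization()),
                       RemlOptions(compute_se=False))
        assert fit.sigma2_eps > 0

    def test_record_reordering_invariance(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        fit1 = fit_reml(build_design(tiny_additive_ds, spec),
                        RemlOptions(compute_se=False))
        shuffled = DiallelDataset(
            tiny_additive_ds.df.sample(frac=1.0, random_state=0),
            n_strains=4)
        fit2 = fit_reml(build_design(shuffled, spec),
                        RemlOptions(compute_se=False))
        assert fit2.varcomp["a"] == pytest.approx(fit1.varcomp["a"],
                                                  abs=1e-6)
        assert fit2.sigma2_eps == pytest.approx(fit1.sigma2_eps, abs=1e-6)

    def test_strain_relabeling_invariance(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        fit1 = fit_reml(build_design(tiny_additive_ds, spec),
                        RemlOptions(compute_se=False))
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        df = tiny_additive_ds.df.copy()
        df["dam"] = df["dam"].map(perm)
        df["sire"] = df["sire"].map(perm)
        fit2 = fit_reml(build_design(DiallelDataset(df, 4), spec),
                        RemlOptions(compute_se=False))
        assert fit2.varcomp["a"] == pytest.approx(fit1.varcomp["a"],
                                                  abs=1e-6)
        u1 = extract_blups(fit1, "a").values
        u2 = extract_blups(fit2, "a").values
        for old, new in perm.items():
            assert u2[new - 1] == pytest.approx(u1[old - 1], abs=1e-6)

    def test_parametric_bootstrap_consistency(self):
        """Re-estimated additive variance is unbiased at desk scale."""
        rng = np.random.default_rng(7)
        s_a_true, s_e_true = 0.15, 0.08
        spec = ModelSpec(fixed=("mu",), random=("a",))
        estimates = []
        for _ in range(30):
            effects = rng.normal(0, np.sqrt(s_a_true), 4)
            rows = []
            for dam in range(1, 5):
                for sire in range(1, 5):
                    for _ in range(6):
                        latent = 3.5 + effects[dam - 1] + effects[sire - 1] \
                            + rng.normal(0, np.sqrt(s_e_true))
                        rows.append((dam, sire, "F", 1,
                                     int(max(0, round(np.exp(latent))))))
            ds = DiallelDataset(pd.DataFrame(
                rows, columns=["dam", "sire", "sex", "block", "fitness"]),
                n_strains=4)
            fit = fit_reml(build_design(ds, spec),
                           RemlOptions(compute_se=False))
            estimates.append(fit.varcomp["a"])
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - s_a_true) < 2.5 * mc_se + 0.02


class TestBlupContracts:
    def test_zero_variance_gives_zero_blups(self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=("a",))
        d = build_design(tiny_additive_ds, spec)
        # evaluate at a pinned point: variance exactly zero for 'a'
        fit = fit_reml(d, RemlOptions(start=np.array([0.0, 0.2]),
                                      max_iter=0, compute_se=False))
        assert fit.varcomp["a"] == 0.0
        assert np.all(extract_blups(fit, "a").values == 0.0)

    def test_negative_variance_blups_refused(self, small_sim):
        ds, _ = small_sim
        spec = ModelSpec.full_sexed()
        fit = fit_reml(build_design(ds, spec), RemlOptions(compute_se=False))
        negative = [t for t, v in fit.varcomp.items() if v < 0]
        assert negative, "full model on this fixture has a negative component"
        with pytest.raises(ValueError, match="negative"):
            extract_blups(fit, negative[0])

    def test_unknown_term_rejected(self, tiny_additive_ds):
        fit = fit_reml(build_design(tiny_additive_ds,
                                    ModelSpec(fixed=("mu",), random=("a",))),
                       RemlOptions(compute_se=False))
        with pytest.raises(KeyError):
            extract_blups(fit, "b3")


class TestConditionalResiduals:
    def test_intercept_only_residuals_are_centered_response(
            self, tiny_additive_ds):
        spec = ModelSpec(fixed=("mu",), random=())
        d = build_design(tiny_additive_ds, spec)
        fit = fit_reml(d, RemlOptions(compute_se=False))
        rd = conditional_residuals(fit, remove=())
        assert np.allclose(rd.residuals, d.y - d.y.mean(), atol=1e-8)

    def test_block_effect_removed(self):
        cfg = SimulationConfig(seed=21, n_strains=8, replicates=3,
                               block_effects=(0.0, 1.5), missingness=0.0)
        ds, _ = generate_diallel(cfg)
        fit = fit_reml(build_design(ds, ModelSpec.residualization()),
                       RemlOptions(compute_se=False))
        rd = conditional_residuals(fit, remove=("x", "b3"))
        df = rd.ds.df
        b1 = rd.residuals[(df["block"] == 1).to_numpy()].mean()
        b2 = rd.residuals[(df["block"] == 2).to_numpy()].mean()
        assert abs(b1 - b2) < 0.05  # vs the injected 1.5 log-unit gap

    def test_additive_blup_removal_reduces_strain_projection(self):
        cfg = SimulationConfig(seed=22, n_strains=8, n_sa_loci=0,
                               n_sc_loci=12, n_load_loci=0, alpha_scale=0.3,
                               dominance_mode="additive", replicates=3,
                               missingness=0.0)
        ds, _ = generate_diallel(cfg)
        spec = ModelSpec.residualization(remove_sc_additive=True)
        d = build_design(ds, spec)
        fit = fit_reml(d, RemlOptions(compute_se=False))
        base = d.y - d.X @ fit.beta
        rd = conditional_residuals(fit, remove=("x", "a", "b3"))
        proj_before = np.abs(d.Z["a"].T @ base).max()
        proj_after = np.abs(d.Z["a"].T @ rd.residuals).max()
        assert proj_after < 0.1 * proj_before

    def test_unknown_term_in_remove_rejected(self, tiny_additive_ds):
        fit = fit_reml(build_design(tiny_additive_ds,
                                    ModelSpec(fixed=("mu",), random=("a",))),
                       RemlOptions(compute_se=False))
        with pytest.raises(KeyError):
            conditional_residuals(fit, remove=("b3",))

    def test_mean_residual_near_zero(self, small_sim):
        ds, _ = small_sim
        fit = fit_reml(build_design(ds, ModelSpec.residualization()),
                       RemlOptions(compute_se=False))
        rd = conditional_residuals(fit, remove=("x", "b3"))
        assert abs(rd.residuals.mean()) < 1e-6
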