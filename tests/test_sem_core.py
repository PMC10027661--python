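"""SEM core: standardization, log-posterior oracle, sampler contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import soilsem as ss
from soilsem.errors import (
    ConfigurationError,
    DegenerateColumnError,
    DomainError,
    ShapeError,
)
from soilsem.sem_core import (
    McmcConfig,
    PosteriorDraws,
    SemSpec,
    log_unnormalized_posterior,
    sample_posterior,
    standardize,
    summarize_effects,
)
from soilsem.tables import MANIFEST_NAMES, ManifestTable


def tiny_spec(n_latents: int, manifests_per_latent: int, with_path: bool):
    """A 1- or 2-latent spec for oracle checks."""
    latents = ("f1", "f2")[:n_latents]
    pattern = {}
    anchors = {}
    for l in latents:
        for k in range(manifests_per_latent):
            m = f"{l}_m{k}"
            pattern[m] = l
            if k == 0:
                anchors[l] = m
    if with_path and n_latents == 2:
        exo, paths = ("f1",), (("f1", "f2"),)
    else:
        exo, paths = latents, ()
    return SemSpec(latents=latents, exogenous=exo, paths=paths,
                   loading_pattern=pattern, anchors=anchors)


def random_tiny_state(spec, n, J, rng):
    manifests = tuple(spec.loading_pattern)
    p = len(manifests)
    L = len(spec.latents)
    state = {
        "alpha": rng.normal(0, 0.5, (J, p)),
        "omega": rng.normal(0, 1, (n, L)),
        "lam": rng.normal(0.8, 0.3, p),
        "gamma": {e: rng.normal() for e in spec.paths},
        "tau_eps": rng.gamma(4, 0.5, p),
        "tau_zeta": rng.gamma(4, 0.5, len(spec.endogenous)),
        "phi": rng.uniform(-0.8, 0.8),
        "sigma_alpha": rng.uniform(0.2, 3.0),
    }
    # respect the anchor constraint so states are reachable by the sampler
    for k, m in enumerate(manifests):
        if spec.anchors.get(spec.loading_pattern[m]) == m:
            state["lam"][k] = 1.0
    return state, manifests


def oracle_log_posterior(state, Y, spec, manifests, pit_index):
    """Independent sum-of-log-densities oracle built on scipy.stats."""
    n, p = Y.shape
    lat_pos = {l: k for k, l in enumerate(spec.latents)}
    lam = state["lam"]
    omega = state["omega"]
    alpha = state["alpha"]
    total = 0.0
    # measurement
    for m_idx, m in enumerate(manifests):
        mu = alpha[pit_index, m_idx] + lam[m_idx] * omega[:, lat_pos[spec.loading_pattern[m]]]
        sd = 1.0 / np.sqrt(state["tau_eps"][m_idx])
        total += stats.norm.logpdf(Y[:, m_idx], mu, sd).sum()
    # structural
    for k, l in enumerate(spec.endogenous):
        pred = np.zeros(n)
        for (s, d), g in state["gamma"].items():
            if d == l:
                pred += g * omega[:, lat_pos[s]]
        sd = 1.0 / np.sqrt(state["tau_zeta"][k])
        total += stats.norm.logpdf(omega[:, lat_pos[l]], pred, sd).sum()
    # exogenous latents
    exo_cols = [lat_pos[l] for l in spec.exogenous]
    if len(exo_cols) == 2:
        cov = np.array([[1.0, state["phi"]], [state["phi"], 1.0]])
        total += stats.multivariate_normal.logpdf(
            omega[:, exo_cols], mean=np.zeros(2), cov=cov).sum()
        total += stats.uniform.logpdf(state["phi"], -1, 2)
    else:
        total += stats.norm.logpdf(omega[:, exo_cols[0]]).sum()
    # intercept hierarchy
    total += stats.norm.logpdf(alpha, 0, state["sigma_alpha"]).sum()
    total += stats.uniform.logpdf(
        state["sigma_alpha"], 0, spec.prior.sigma_alpha_upper)
    # coefficient priors
    sd0 = np.sqrt(spec.prior.coef_variance)
    anchor = [spec.anchors.get(spec.loading_pattern[m]) == m for m in manifests]
    total += stats.norm.logpdf(lam[~np.array(anchor)], 0, sd0).sum()
    for g in state["gamma"].values():
        total += stats.norm.logpdf(g, 0, sd0)
    # precision priors (shape-rate Gamma)
    a, b = spec.prior.error_shape, spec.prior.error_rate
    for tau in np.concatenate([state["tau_eps"], state["tau_zeta"]]):
        total += stats.gamma.logpdf(tau, a, scale=1.0 / b)
    return float(total)


class TestStandardize:
    def test_closed_form_column(self):
        mt = ManifestTable(
            data=pd.DataFrame({"t50": [1.0, 2.0, 3.0]}),
            pit_id=["a", "a", "b"], land_use=["MP", "MP", "PG"],
        )
        Z, record = standardize(mt)
        np.testing.assert_allclose(
            Z[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert record.loc[0, "mean"] == pytest.approx(2.0)

    def test_idempotent_on_standardized_input(self, default_manifests):
        Z, _ = standardize(default_manifests)
        again = ManifestTable(
            data=pd.DataFrame(Z, columns=default_manifests.data.columns),
            pit_id=default_manifests.pit_id,
            land_use=default_manifests.land_use,
        )
        Z2, _ = standardize(again)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_constant_column_rejected(self):
        mt = ManifestTable(
            data=pd.DataFrame({"t50": [5.0, 5.0, 5.0]}),
            pit_id=["a", "a", "b"], land_use=["MP", "MP", "PG"],
        )
        with pytest.raises(DegenerateColumnError, match="t50"):
            standardize(mt)


class TestLogPosterior:
    @pytest.mark.parametrize("n_latents,mpl,with_path", [
        (1, 2, False), (2, 2, False), (2, 3, True),
    ])
    def test_matches_independent_oracle(self, n_latents, mpl, with_path):
        rng = np.random.default_rng(8)
        for _ in range(10):
            spec = tiny_spec(n_latents, mpl, with_path)
            n, J = 4, 2
            state, manifests = random_tiny_state(spec, n, J, rng)
            pit_index = rng.integers(0, J, n)
            Y = rng.normal(0, 1, (n, len(manifests)))
            got = log_unnormalized_posterior(state, Y, spec, manifests, pit_index)
            want = oracle_log_posterior(state, Y, spec, manifests, pit_index)
            assert got == pytest.approx(want, abs=1e-10)

    def test_zero_loadings_reduce_to_intercept_model(self):
        """With all loadings and latents zero the measurement term is the
        plain Gaussian likelihood around the pit intercepts."""
        rng = np.random.default_rng(3)
        spec = tiny_spec(1, 2, False)
        state, manifests = random_tiny_state(spec, 5, 1, rng)
        state["lam"] = np.zeros(2)
        state["omega"] = np.zeros((5, 1))
        pit_index = np.zeros(5, dtype=int)
        Y = rng.normal(0, 1, (5, 2))
        got = log_unnormalized_posterior(state, Y, spec, manifests, pit_index)
        want = oracle_log_posterior(state, Y, spec, manifests, pit_index)
        assert got == pytest.approx(want, abs=1e-10)
        # isolate the measurement term by zeroing the residual sum for one
        # manifest: moving y onto the intercept changes the log density by
        # exactly +0.5 * tau * ss of that manifest
        tau0 = state["tau_eps"][0]
        ss_resid = float(np.sum((Y[:, 0] - state["alpha"][0, 0]) ** 2))
        Y2 = Y.copy()
        Y2[:, 0] = state["alpha"][0, 0]
        got2 = log_unnormalized_posterior(state, Y2, spec, manifests, pit_index)
        assert got2 - got == pytest.approx(0.5 * tau0 * ss_resid, abs=1e-9)

    def test_error_sd_doubling_changes_normalization(self):
        """Halving a precision at fixed residuals shifts the log density by
        the closed-form Gaussian normalization difference."""
        rng = np.random.default_rng(4)
        spec = tiny_spec(1, 2, False)
        n = 6
        state, manifests = random_tiny_state(spec, n, 1, rng)
        pit_index = np.zeros(n, dtype=int)
        Y = rng.normal(0, 1, (n, 2))
        base = log_unnormalized_posterior(state, Y, spec, manifests, pit_index)
        tau = state["tau_eps"][0]
        state2 = dict(state)
        state2["tau_eps"] = state["tau_eps"].copy()
        state2["tau_eps"][0] = tau / 4.0  # double the error sd
        mu = state["alpha"][pit_index, 0] + state["lam"][0] * state["omega"][:, 0]
        ss_resid = float(np.sum((Y[:, 0] - mu) ** 2))
        a, b = spec.prior.error_shape, spec.prior.error_rate
        delta = (
            0.5 * n * np.log(0.25)          # likelihood normalization
            - 0.5 * (tau / 4 - tau) * ss_resid
            + (a - 1) * np.log(0.25) - b * (tau / 4 - tau)  # prior
        )
        got = log_unnormalized_posterior(state2, Y, spec, manifests, pit_index)
        assert got - base == pytest.approx(delta, abs=1e-9)

    def test_domain_and_shape_errors(self):
        rng = np.random.default_rng(5)
        spec = tiny_spec(1, 2, False)
        state, manifests = random_tiny_state(spec, 4, 1, rng)
        Y = rng.normal(0, 1, (4, 2))
        pit = np.zeros(4, dtype=int)
        bad = dict(state)
        bad["tau_eps"] = np.array([-1.0, 1.0])
        with pytest.raises(DomainError):
            log_unnormalized_posterior(bad, Y, spec, manifests, pit)
        bad = dict(state)
        bad["omega"] = state["omega"][:, :0]
        with pytest.raises(ShapeError):
            log_unnormalized_posterior(bad, Y, spec, manifests, pit)


class TestSampler:
    def test_retained_count_bookkeeping(self):
        cfg = McmcConfig(chains=3, iterations=50_000, burn_in=30_000, thin=16)
        assert cfg.retained_per_chain == 1250
        assert cfg.chains * cfg.retained_per_chain == 3750

    def test_retained_count_on_actual_reduced_run(self, default_manifests):
        cfg = McmcConfig(chains=2, iterations=300, burn_in=100, thin=4,
                         base_seed=0)
        draws = sample_posterior(default_manifests, SemSpec.default(), cfg)
        assert draws.draws.shape[:2] == (2, cfg.retained_per_chain)
        assert cfg.retained_per_chain == 50

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            McmcConfig(iterations=1000, burn_in=1000)

    def test_same_seed_bit_identical(self, default_manifests):
        cfg = McmcConfig(chains=2, iterations=400, burn_in=200, thin=2,
                         base_seed=7)
        a = sample_posterior(default_manifests, SemSpec.default(), cfg)
        b = sample_posterior(default_manifests, SemSpec.default(), cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_pit_relabeling_leaves_draws_unchanged(self, default_manifests):
        renamed = ManifestTable(
            data=default_manifests.data.copy(),
            pit_id=np.array([f"pit_{p}" for p in default_manifests.pit_id]),
            land_use=default_manifests.land_use,
        )
        cfg = McmcConfig(chains=1, iterations=300, burn_in=100, thin=2,
                         base_seed=3)
        a = sample_posterior(default_manifests, SemSpec.default(), cfg)
        b = sample_posterior(renamed, SemSpec.default(), cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_conjugate_loading_matches_closed_form(self):
        """With latents, precisions and intercepts held fixed, the sampled
        free loading is Normal-Normal conjugate; its posterior mean must
        match the closed form within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(21)
        spec = tiny_spec(1, 2, False)
        n = 40
        omega = rng.normal(0, 1, (n, 1))
        lam_true = 0.7
        tau = np.array([4.0, 4.0])
        Y = np.column_stack([
            omega[:, 0] + rng.normal(0, 0.5, n),
            lam_true * omega[:, 0] + rng.normal(0, 0.5, n),
        ])
        fixed = {
            "omega": omega, "tau_eps": tau, "alpha": np.zeros((1, 2)),
            "sigma_alpha": 1.0, "tau_zeta": np.zeros(0),
        }
        cfg = McmcConfig(chains=1, iterations=4000, burn_in=0, thin=1,
                         base_seed=2)
        draws = sample_posterior(
            Y, spec, cfg, pit_index=np.zeros(n, dtype=int),
            manifests=("f1_m0", "f1_m1"), fixed=fixed)
        x = draws.pooled("lambda[f1_m1]")
        prec = tau[1] * float(omega[:, 0] @ omega[:, 0]) \
            + 1.0 / spec.prior.coef_variance
        mean = tau[1] * float(omega[:, 0] @ Y[:, 1]) / prec
        mc_se = x.std() / np.sqrt(len(x))
        assert abs(x.mean() - mean) < 3 * mc_se + 1e-12
        assert x.std() == pytest.approx(1.0 / np.sqrt(prec), rel=0.1)

    def test_prior_recovery_without_data(self):
        """With no manifests observed the sampler explores the joint prior:
        the marginal sd of a path coefficient approaches the N(0, 100)
        prior sd."""
        spec = SemSpec.default()
        cfg = McmcConfig(chains=1, iterations=60_000, burn_in=2000, thin=1,
                         base_seed=7)
        draws = sample_posterior(
            np.zeros((2, 0)), spec, cfg,
            pit_index=np.zeros(2, dtype=int), manifests=())
        g = draws.pooled("gamma[acidification->fertility]")
        assert g.std() == pytest.approx(10.0, rel=0.05)


class TestSummarizeEffects:
    def _draws_for_paths(self, values_for_first):
        spec = SemSpec.default()
        names = [f"gamma[{s}->{d}]" for s, d in spec.paths]
        n = len(values_for_first)
        arr = np.ones((1, n, len(names)))
        arr[0, :, 0] = values_for_first
        return PosteriorDraws(draws=arr, names=tuple(names)), spec

    def test_quantile_rule_oracle(self):
        draws, spec = self._draws_for_paths(np.arange(1.0, 101.0))
        eff = summarize_effects(draws, spec).set_index("path")
        row = eff.loc["acidification->fertility"]
        assert row["median"] == pytest.approx(50.5)
        assert row["lower"] == pytest.approx(3.475)
        assert row["upper"] == pytest.approx(97.525)

    def test_constant_draws(self):
        draws, spec = self._draws_for_paths(np.full(50, 2.5))
        row = summarize_effects(draws, spec).set_index("path").loc[
            "acidification->fertility"]
        assert row["median"] == row["lower"] == row["upper"] == 2.5

    def test_symmetric_draws_median_near_mean(self, rng):
        x = rng.standard_normal(20_001) + 0.3
        draws, spec = self._draws_for_paths(x)
        row = summarize_effects(draws, spec).set_index("path").loc[
            "acidification->fertility"]
        assert row["median"] == pytest.approx(x.mean(), abs=0.02)

    def test_unknown_path_raises(self, quick_fit):
        spec = SemSpec.default()
        other = SemSpec.default("methods")
        with pytest.raises(KeyError):
            summarize_effects(quick_fit, other)


class TestSpecValidation:
    def test_cyclic_paths_rejected(self):
        with pytest.raises(ConfigurationError):
            SemSpec(paths=(
                ("fertility", "microorganisms"),
                ("microorganisms", "fertility"),
            ))

    def test_path_into_exogenous_rejected(self):
        with pytest.raises(ConfigurationError):
            SemSpec(paths=(("fertility", "weathering"),))

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            SemSpec.default("figure4")

    def test_methods_preset_has_six_paths(self):
        spec = SemSpec.default("methods")
        assert len(spec.paths) == 6
        assert ("microorganisms", "fertility") in spec.paths
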