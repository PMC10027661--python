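"""Hierarchical Bayesian structural equation model and MCMC sampler.

Model
-----
Five latent constructs: two exogenous (weathering xi1, acidification xi2)
and three endogenous (fertility eta1, microorganisms eta2, SOC persistence
eta3).  The exogenous latents are bivariate standard normal with free
correlation phi; each endogenous latent follows a structural equation

    eta = sum_parents gamma_edge * parent + zeta,   zeta ~ N(0, 1/tau_zeta)

over a user-selected acyclic path set.  The measurement model links the
p manifest variables to the latent scores through

    y_i = alpha_{j(i)} + Lambda omega_i + eps_i,

with a soil-pit-specific intercept alpha_j per manifest, loading matrix
Lambda following the fixed simple-structure pattern (each manifest loads
on exactly one latent; one anchor loading per latent is fixed to +1 for
scale identification), and independent Gaussian errors with precisions
tau_eps.

Priors: N(0, 100) on free loadings and path coefficients, Gamma(shape 6,
rate 10) on the error precisions (measurement and structural),
alpha_j ~ N(0, sigma_alpha^2) with sigma_alpha ~ U(0, 100), and
phi ~ U(-1, 1).

Sampling is systematic-scan Metropolis-within-Gibbs: intercepts, latent
scores, loadings, path coefficients and precisions have conjugate Gaussian
or Gamma full conditionals and are Gibbs-updated; phi and sigma_alpha take
Gaussian random-walk Metropolis steps whose step sizes adapt only during
burn-in.  Draws are deterministic functions of (data, spec, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import (
    ConfigurationError,
    DegenerateColumnError,
    DomainError,
    ShapeError,
)
from .tables import ANCHORS, EXOGENOUS, LATENTS, MANIFEST_LATENTS, ManifestTable

#: path presets.  "figure3" carries the four reported effects;
#: "methods" is the alternative recursive system (fertility regressed on
#: weathering, acidification and microorganisms; microorganisms on
#: acidification; SOC on weathering and microorganisms).
PATH_PRESETS: dict[str, tuple[tuple[str, str], ...]] = {
    "figure3": (
        ("acidification", "fertility"),
        ("fertility", "microorganisms"),
        ("weathering", "soc"),
        ("acidification", "soc"),
    ),
    "methods": (
        ("weathering", "fertility"),
        ("acidification", "fertility"),
        ("microorganisms", "fertility"),
        ("acidification", "microorganisms"),
        ("weathering", "soc"),
        ("microorganisms", "soc"),
    ),
}


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters (see module docstring)."""

    coef_variance: float = 100.0        # N(0, 100) on gamma and free Lambda
    error_shape: float = 6.0            # Gamma(6, 10) on precisions
    error_rate: float = 10.0
    sigma_alpha_upper: float = 100.0    # U(0, 100) on the intercept sd

    def __post_init__(self) -> None:
        if min(self.coef_variance, self.error_shape, self.error_rate,
               self.sigma_alpha_upper) <= 0:
            raise ConfigurationError("prior hyper-parameters must be positive")


@dataclass(frozen=True)
class SemSpec:
    """Latent structure, loading pattern and priors of one model."""

    latents: tuple[str, ...] = LATENTS
    exogenous: tuple[str, ...] = EXOGENOUS
    paths: tuple[tuple[str, str], ...] = PATH_PRESETS["figure3"]
    loading_pattern: dict[str, str] = field(
        default_factory=lambda: dict(MANIFEST_LATENTS)
    )
    anchors: dict[str, str] = field(default_factory=lambda: dict(ANCHORS))
    prior: PriorSpec = field(default_factory=PriorSpec)
    path_preset: str = "figure3"

    @classmethod
    def default(cls, preset: str = "figure3") -> "SemSpec":
        if preset not in PATH_PRESETS:
            raise ConfigurationError(
                f"unknown path preset {preset!r}; choose from {sorted(PATH_PRESETS)}"
            )
        return cls(paths=PATH_PRESETS[preset], path_preset=preset)

    def __post_init__(self) -> None:
        if len(self.exogenous) not in (1, 2):
            raise ConfigurationError("1 or 2 exogenous latents supported")
        for lat in self.exogenous:
            if lat not in self.latents:
                raise ConfigurationError(f"unknown exogenous latent {lat!r}")
        for src, dst in self.paths:
            if src not in self.latents or dst not in self.latents:
                raise ConfigurationError(f"unknown latent in path {src}->{dst}")
            if dst in self.exogenous:
                raise ConfigurationError(f"path into exogenous latent {dst!r}")
        self._check_acyclic()
        for lat in self.latents:
            anchor = self.anchors.get(lat)
            if anchor is not None and self.loading_pattern.get(anchor) != lat:
                raise ConfigurationError(
                    f"anchor {anchor!r} not assigned to latent {lat!r}"
                )
        used = [l for l in self.loading_pattern.values()]
        for lat, anchor in self.anchors.items():
            if lat in used and anchor is None:
                raise ConfigurationError(f"latent {lat!r} lacks an anchor")
        for m, lat in self.loading_pattern.items():
            if lat not in self.latents:
                raise ConfigurationError(
                    f"manifest {m!r} assigned to unknown latent {lat!r}"
                )

    def _check_acyclic(self) -> None:
        endo = [l for l in self.latents if l not in self.exogenous]
        parents = {l: [s for s, d in self.paths if d == l] for l in endo}
        placed = set(self.exogenous)
        remaining = list(endo)
        while remaining:
            ready = [l for l in remaining if all(p in placed for p in parents[l])]
            if not ready:
                raise ConfigurationError(f"cyclic path set among {remaining}")
            for l in ready:
                placed.add(l)
                remaining.remove(l)

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(l for l in self.latents if l not in self.exogenous)


@dataclass(frozen=True)
class McmcConfig:
    """MCMC schedule: chains, iterations, burn-in, thinning, seeding."""

    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 30_000
    thin: int = 16
    base_seed: int = 0
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigurationError("chains must be >= 1")
        if self.burn_in >= self.iterations:
            raise ConfigurationError("burn_in must be < iterations")
        if self.burn_in < 0 or self.thin < 1:
            raise ConfigurationError("burn_in >= 0 and thin >= 1 required")

    @property
    def retained_per_chain(self) -> int:
        # iterations t = burn_in, burn_in + thin, ... are retained
        return -(-(self.iterations - self.burn_in) // self.thin)


@dataclass
class PosteriorDraws:
    """Posterior draws: array (chains, retained, parameters) plus names."""

    draws: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ShapeError("draws must be (chains, retained, len(names))")
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("parameter names must be unique")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, retained)."""
        try:
            k = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, :, k]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Flat (chain, iteration, parameter, value) table."""
        c, r, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), r * p),
            "iteration": np.tile(np.repeat(np.arange(r), p), c),
            "parameter": np.tile(np.asarray(self.names, dtype=object), c * r),
            "value": self.draws.reshape(-1),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        names = tuple(dict.fromkeys(df["parameter"]))
        chains = sorted(df["chain"].unique())
        r = df["iteration"].nunique()
        arr = np.empty((len(chains), r, len(names)))
        pivot = df.pivot_table(
            index=["chain", "iteration"], columns="parameter",
            values="value", sort=False,
        )[list(names)]
        for ci, c in enumerate(chains):
            arr[ci] = pivot.loc[c].to_numpy()
        return cls(draws=arr, names=names)


def standardize(
    manifests: ManifestTable,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Column-standardize the manifest matrix (mean 0, sd 1).

    Returns the standardized array and a scaling record (manifest, mean,
    sd) permitting exact back-transformation.  Population sd (ddof 0).
    """
    X = manifests.data.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    for j, col in enumerate(manifests.data.columns):
        if sd[j] == 0 or not np.isfinite(sd[j]):
            raise DegenerateColumnError(
                f"manifest column {col!r} is constant; cannot standardize"
            )
    record = pd.DataFrame({
        "manifest": list(manifests.data.columns), "mean": mean, "sd": sd,
    })
    return (X - mean) / sd, record


# ---------------------------------------------------------------------------
# model internals
# ---------------------------------------------------------------------------


class _Model:
    """Index bookkeeping shared by the log-density and the sampler."""

    def __init__(self, spec: SemSpec, manifests: tuple[str, ...],
                 pit_index: np.ndarray, n_pits: int):
        self.spec = spec
        self.manifests = manifests
        self.p = len(manifests)
        self.L = len(spec.latents)
        self.lat_pos = {l: k for k, l in enumerate(spec.latents)}
        for m in manifests:
            if m not in spec.loading_pattern:
                raise ConfigurationError(f"manifest {m!r} not in loading pattern")
        self.lat_idx = np.array(
            [self.lat_pos[spec.loading_pattern[m]] for m in manifests], dtype=int
        )
        self.anchor_mask = np.array(
            [spec.anchors.get(spec.loading_pattern[m]) == m for m in manifests],
            dtype=bool,
        )
        self.exo_idx = np.array([self.lat_pos[l] for l in spec.exogenous])
        self.endo = spec.endogenous
        self.endo_idx = np.array([self.lat_pos[l] for l in self.endo])
        self.parents = {
            l: [s for s, d in spec.paths if d == l] for l in self.endo
        }
        self.edges = tuple(spec.paths)
        self.pit_index = np.asarray(pit_index, dtype=int)
        self.J = n_pits

    def loading_matrix(self, lam: np.ndarray) -> np.ndarray:
        Lam = np.zeros((self.p, self.L))
        Lam[np.arange(self.p), self.lat_idx] = lam
        return Lam

    def structural_matrix(self, gamma: dict) -> np.ndarray:
        """B with B[child, parent] = coefficient; omega' = B omega + noise."""
        B = np.zeros((self.L, self.L))
        for (src, dst), g in gamma.items():
            B[self.lat_pos[dst], self.lat_pos[src]] = g
        return B

    def latent_precision(self, gamma: dict, tau_zeta: np.ndarray,
                         phi: float) -> np.ndarray:
        """Joint prior precision of omega implied by the recursive system."""
        B = self.structural_matrix(gamma)
        IB = np.eye(self.L) - B
        psi_inv = np.zeros((self.L, self.L))
        if len(self.exo_idx) == 2:
            det = 1.0 - phi * phi
            i, j = self.exo_idx
            psi_inv[i, i] = psi_inv[j, j] = 1.0 / det
            psi_inv[i, j] = psi_inv[j, i] = -phi / det
        else:
            psi_inv[self.exo_idx[0], self.exo_idx[0]] = 1.0
        for k, l in zip(self.endo_idx, self.endo):
            psi_inv[k, k] = tau_zeta[self.endo.index(l)]
        return IB.T @ psi_inv @ IB


def _as_gamma_dict(spec: SemSpec, gamma) -> dict:
    if isinstance(gamma, dict):
        return gamma
    return dict(zip(spec.paths, np.asarray(gamma, dtype=float)))


def log_unnormalized_posterior(
    state: dict,
    data: np.ndarray,
    spec: SemSpec,
    manifests: tuple[str, ...],
    pit_index: np.ndarray,
) -> float:
    """Log unnormalized posterior density of a full state.

    ``state`` holds: alpha (J, p), omega (n, L), lam (p,), gamma (dict
    edge -> float or array in path order), tau_eps (p,), tau_zeta
    (n_endogenous,), phi, sigma_alpha.  The value is the sum of the
    measurement, structural, exogenous-latent, intercept-hierarchy and
    prior log densities (all normalizing constants included).
    """
    Y = np.asarray(data, dtype=float)
    n, p = Y.shape
    alpha_arr = np.asarray(state["alpha"], dtype=float)
    if alpha_arr.ndim != 2:
        raise ShapeError("alpha must be (n_pits, n_manifests)")
    model = _Model(spec, manifests, pit_index, alpha_arr.shape[0])
    alpha = alpha_arr
    omega = np.asarray(state["omega"], dtype=float)
    lam = np.asarray(state["lam"], dtype=float)
    gamma = _as_gamma_dict(spec, state["gamma"])
    tau_eps = np.asarray(state["tau_eps"], dtype=float)
    tau_zeta = np.asarray(state["tau_zeta"], dtype=float)
    phi = float(state["phi"])
    sigma_alpha = float(state["sigma_alpha"])

    if omega.shape != (n, model.L) or lam.shape != (p,):
        raise ShapeError("omega/lam dimensions do not match data and spec")
    if alpha.shape != (model.J, p):
        raise ShapeError("alpha must be (n_pits, n_manifests)")
    if np.any(tau_eps <= 0) or np.any(tau_zeta <= 0):
        raise DomainError("precisions must be positive")
    if not -1.0 < phi < 1.0:
        raise DomainError("phi must lie in (-1, 1)")
    if not 0.0 < sigma_alpha < spec.prior.sigma_alpha_upper:
        raise DomainError("sigma_alpha outside its prior support")

    ll = 0.0
    # (a) measurement model
    mu = alpha[model.pit_index] + omega @ model.loading_matrix(lam).T
    resid2 = (Y - mu) ** 2
    ll += 0.5 * n * np.sum(np.log(tau_eps)) - 0.5 * n * p * math.log(2 * math.pi)
    ll += -0.5 * float(resid2.sum(axis=0) @ tau_eps)
    # (b) structural equations
    for k, l in enumerate(model.endo):
        pred = np.zeros(n)
        for s in model.parents[l]:
            pred += gamma[(s, l)] * omega[:, model.lat_pos[s]]
        r2 = np.sum((omega[:, model.lat_pos[l]] - pred) ** 2)
        ll += 0.5 * n * math.log(tau_zeta[k]) - 0.5 * n * math.log(2 * math.pi)
        ll += -0.5 * tau_zeta[k] * r2
    # (c) exogenous latents
    if len(model.exo_idx) == 2:
        x1 = omega[:, model.exo_idx[0]]
        x2 = omega[:, model.exo_idx[1]]
        det = 1.0 - phi * phi
        quad = np.sum(x1 ** 2 - 2 * phi * x1 * x2 + x2 ** 2) / det
        ll += -n * math.log(2 * math.pi) - 0.5 * n * math.log(det) - 0.5 * quad
    else:
        x1 = omega[:, model.exo_idx[0]]
        ll += -0.5 * n * math.log(2 * math.pi) - 0.5 * np.sum(x1 ** 2)
    # (d) intercept hierarchy
    ll += (
        -0.5 * alpha.size * math.log(2 * math.pi)
        - alpha.size * math.log(sigma_alpha)
        - 0.5 * float(np.sum(alpha ** 2)) / sigma_alpha ** 2
    )
    # (e) priors
    v = spec.prior.coef_variance
    free_lam = lam[~model.anchor_mask]
    coefs = np.concatenate([free_lam, np.array([gamma[e] for e in model.edges])])
    ll += (
        -0.5 * coefs.size * math.log(2 * math.pi * v)
        - 0.5 * float(np.sum(coefs ** 2)) / v
    )
    a, b = spec.prior.error_shape, spec.prior.error_rate
    taus = np.concatenate([tau_eps, tau_zeta])
    ll += float(np.sum(
        a * math.log(b) - math.lgamma(a) + (a - 1) * np.log(taus) - b * taus
    ))
    ll += -math.log(spec.prior.sigma_alpha_upper)  # U(0, upper) on sigma_alpha
    if len(model.exo_idx) == 2:
        ll += -math.log(2.0)                        # U(-1, 1) on phi
    return float(ll)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

#: Metropolis refreshes of phi per Gibbs scan; its conditional given the
#: exogenous scores costs O(n), so extra refreshes are cheap and cut the
#: autocorrelation of phi well below that of a single-step update.
_PHI_STEPS = 10


def _run_chain(
    Y: np.ndarray,
    model: _Model,
    spec: SemSpec,
    cfg: McmcConfig,
    seed: int,
    fixed: dict,
    monitor_alpha: bool,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n, p = Y.shape
    L, J = model.L, model.J
    n_endo = len(model.endo)
    prior = spec.prior
    coef_prec = 1.0 / prior.coef_variance
    a0, b0 = prior.error_shape, prior.error_rate

    # --- initial state (drawn from the seeded stream) ---
    omega = np.asarray(fixed.get("omega", 0.1 * rng.standard_normal((n, L))),
                       dtype=float)
    lam = np.asarray(fixed.get("lam", np.ones(p)), dtype=float).copy()
    lam[model.anchor_mask] = 1.0
    gamma = dict(fixed.get("gamma", {e: 0.0 for e in model.edges}))
    tau_eps = np.asarray(fixed.get("tau_eps", np.full(p, a0 / b0)), dtype=float).copy()
    tau_zeta = np.asarray(
        fixed.get("tau_zeta", np.full(n_endo, a0 / b0)), dtype=float
    ).copy()
    phi = float(fixed.get("phi", 0.0))
    sigma_alpha = float(fixed.get("sigma_alpha", 1.0))
    alpha = np.asarray(fixed.get("alpha", np.zeros((J, p))), dtype=float).copy()

    two_exo = len(model.exo_idx) == 2
    step_phi, step_sig = 0.2, 0.3
    acc_phi = acc_sig = 0

    pit = model.pit_index
    # per-pit row lists for intercept updates
    counts = np.bincount(pit, minlength=J).astype(float) if n else np.zeros(J)

    retained = cfg.retained_per_chain
    names_extra = J * p if monitor_alpha else 0
    n_params = (
        len(model.edges) + int(np.sum(~model.anchor_mask)) + p + n_endo + 2
        + names_extra
    )
    out = np.empty((retained, n_params))
    keep = 0

    def exo_loglik(ph: float) -> float:
        x1 = omega[:, model.exo_idx[0]]
        x2 = omega[:, model.exo_idx[1]]
        det = 1.0 - ph * ph
        quad = float(np.sum(x1 * x1 - 2 * ph * x1 * x2 + x2 * x2)) / det
        return -0.5 * n * math.log(det) - 0.5 * quad

    for t in range(cfg.iterations):
        # 1. pit intercepts
        if "alpha" not in fixed and n and p:
            E = Y - omega @ model.loading_matrix(lam).T
            sums = np.zeros((J, p))
            np.add.at(sums, pit, E)
            prec = 1.0 / sigma_alpha ** 2 + counts[:, None] * tau_eps[None, :]
            mean = (tau_eps[None, :] * sums) / prec
            alpha = mean + rng.standard_normal((J, p)) / np.sqrt(prec)

        # 2. latent scores (joint per observation; shared precision)
        if "omega" not in fixed:
            K = model.latent_precision(gamma, tau_zeta, phi)
            Lam = model.loading_matrix(lam)
            A = K + (Lam * tau_eps[:, None]).T @ Lam
            cF, low = cho_factor(A, lower=True)
            R = (Y - alpha[pit]) * tau_eps[None, :]
            b = R @ Lam
            mean = cho_solve((cF, low), b.T).T
            z = rng.standard_normal((L, n))
            omega = mean + solve_triangular(cF, z, lower=True, trans="T").T

        # 3. loadings (free entries; conjugate scalar normals)
        if "lam" not in fixed and n and p:
            C = omega[:, model.lat_idx]                      # (n, p)
            resid = Y - alpha[pit]
            sxx = np.einsum("ij,ij->j", C, C)
            sxy = np.einsum("ij,ij->j", C, resid)
            prec = tau_eps * sxx + coef_prec
            mean = tau_eps * sxy / prec
            draw = mean + rng.standard_normal(p) / np.sqrt(prec)
            lam = np.where(model.anchor_mask, 1.0, draw)

        # 4. path coefficients (conjugate, jointly per endogenous latent)
        if "gamma" not in fixed:
            for k, l in enumerate(model.endo):
                pa = model.parents[l]
                if not pa:
                    continue
                X = omega[:, [model.lat_pos[s] for s in pa]]
                y = omega[:, model.lat_pos[l]]
                P = tau_zeta[k] * X.T @ X + coef_prec * np.eye(len(pa))
                m = np.linalg.solve(P, tau_zeta[k] * X.T @ y)
                cP = np.linalg.cholesky(P)
                draw = m + solve_triangular(
                    cP, rng.standard_normal(len(pa)), lower=True, trans="T"
                )
                for s, g in zip(pa, draw):
                    gamma[(s, l)] = float(g)

        # 5. precisions
        if "tau_eps" not in fixed and n and p:
            mu = alpha[pit] + omega @ model.loading_matrix(lam).T
            ss = np.sum((Y - mu) ** 2, axis=0)
            tau_eps = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ss))
        if "tau_zeta" not in fixed:
            for k, l in enumerate(model.endo):
                pred = np.zeros(n)
                for s in model.parents[l]:
                    pred = pred + gamma[(s, l)] * omega[:, model.lat_pos[s]]
                ss = float(np.sum((omega[:, model.lat_pos[l]] - pred) ** 2))
                tau_zeta[k] = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ss))

        # 6. exogenous correlation: random-walk Metropolis on the Fisher-z
        # scale (well-behaved near the +-1 boundary), refreshed several
        # times per scan (the conditional is cheap).  The Jacobian of
        # phi = tanh(z) contributes log(1 - phi^2).
        if two_exo and "phi" not in fixed:
            cur_lp = exo_loglik(phi) + math.log1p(-phi * phi)
            for _ in range(_PHI_STEPS):
                z = math.atanh(phi) + step_phi * rng.standard_normal()
                prop = math.tanh(z)
                if not -1.0 < prop < 1.0:  # tanh saturation at float limits
                    continue
                new_lp = exo_loglik(prop) + math.log1p(-prop * prop)
                if math.log(rng.random()) < new_lp - cur_lp:
                    phi, cur_lp = prop, new_lp
                    acc_phi += 1

        # 7. intercept-hierarchy sd.  Conditioning on alpha couples
        # sigma_alpha to 171 intercepts and mixes poorly (the hierarchical
        # funnel), so sigma_alpha is updated from its conditional with
        # alpha marginalized out — per (pit, manifest) the pit mean of the
        # measurement residuals is N(0, sigma^2 + 1/(n_j tau_m)) — via a
        # Metropolis step, after which alpha is redrawn given the new sd
        # (a joint (sigma_alpha, alpha) block).
        if "sigma_alpha" not in fixed and n and p:
            E = Y - omega @ model.loading_matrix(lam).T
            sums = np.zeros((J, p))
            np.add.at(sums, pit, E)
            ebar = sums / np.maximum(counts[:, None], 1.0)
            noise_var = 1.0 / (np.maximum(counts[:, None], 1.0)
                               * tau_eps[None, :])

            def sd_loglik(s: float) -> float:
                v = s * s + noise_var
                return float(-0.5 * np.sum(np.log(v) + ebar ** 2 / v))

            prop = sigma_alpha + step_sig * rng.standard_normal()
            if 0.0 < prop < prior.sigma_alpha_upper:
                if math.log(rng.random()) < sd_loglik(prop) - sd_loglik(sigma_alpha):
                    sigma_alpha = prop
                    acc_sig += 1
            if "alpha" not in fixed:
                prec = 1.0 / sigma_alpha ** 2 + counts[:, None] * tau_eps[None, :]
                mean = (tau_eps[None, :] * sums) / prec
                alpha = mean + rng.standard_normal((J, p)) / np.sqrt(prec)
        elif "sigma_alpha" not in fixed:
            ssq = float(np.sum(alpha ** 2))
            prop = sigma_alpha + step_sig * rng.standard_normal()
            if 0.0 < prop < prior.sigma_alpha_upper:
                cur = -alpha.size * math.log(sigma_alpha) \
                    - 0.5 * ssq / sigma_alpha ** 2
                new = -alpha.size * math.log(prop) - 0.5 * ssq / prop ** 2
                if math.log(rng.random()) < new - cur:
                    sigma_alpha = prop
                    acc_sig += 1

        # adapt Metropolis steps during burn-in only
        if t < cfg.burn_in and (t + 1) % cfg.adapt_interval == 0:
            target = 0.44
            rate = acc_phi / (cfg.adapt_interval * _PHI_STEPS)
            step_phi *= math.exp(0.3 * (rate - target))
            step_phi = min(max(step_phi, 1e-3), 2.0)
            rate = acc_sig / cfg.adapt_interval
            step_sig *= math.exp(0.3 * (rate - target))
            step_sig = min(max(step_sig, 1e-3), 50.0)
            acc_phi = acc_sig = 0

        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            vec = [gamma[e] for e in model.edges]
            vec.extend(lam[~model.anchor_mask])
            vec.extend(tau_eps)
            vec.extend(tau_zeta)
            vec.append(phi)
            vec.append(sigma_alpha)
            if monitor_alpha:
                vec.extend(alpha.reshape(-1))
            out[keep] = vec
            keep += 1
    assert keep == retained
    return out


def parameter_names(
    model: _Model, monitor_alpha: bool = False, pit_ids=None
) -> tuple[str, ...]:
    names = [f"gamma[{s}->{d}]" for s, d in model.edges]
    names += [
        f"lambda[{m}]" for m, a in zip(model.manifests, model.anchor_mask) if not a
    ]
    names += [f"tau_eps[{m}]" for m in model.manifests]
    names += [f"tau_zeta[{l}]" for l in model.endo]
    names += ["phi", "sigma_alpha"]
    if monitor_alpha:
        ids = pit_ids if pit_ids is not None else range(model.J)
        names += [f"alpha[{j},{m}]" for j in ids for m in model.manifests]
    return tuple(names)


def sample_posterior(
    data: np.ndarray | ManifestTable,
    spec: SemSpec | None = None,
    cfg: McmcConfig | None = None,
    pit_index: np.ndarray | None = None,
    manifests: tuple[str, ...] | None = None,
    fixed: dict | None = None,
    monitor_alpha: bool = False,
) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    ``data`` is either a (standardized) n x p array with ``pit_index`` and
    ``manifests`` given explicitly, or a :class:`ManifestTable` which is
    standardized internally.  Chain c uses seed ``base_seed + c``; burn-in
    draws are discarded and every ``thin``-th retained, giving
    ``cfg.retained_per_chain`` draws per chain.  ``fixed`` pins named state
    blocks (e.g. ``{"omega": ..., "tau_eps": ...}``) for validation
    sub-models.
    """
    spec = spec or SemSpec.default()
    cfg = cfg or McmcConfig()
    fixed = fixed or {}
    pit_ids = None
    if isinstance(data, ManifestTable):
        Z, _ = standardize(data)
        pits = list(dict.fromkeys(data.pit_id))
        pit_ids = pits
        lut = {pid: i for i, pid in enumerate(pits)}
        pit_index = np.array([lut[pid] for pid in data.pit_id])
        manifests = data.manifests
        Y = Z
    else:
        Y = np.asarray(data, dtype=float)
        if manifests is None:
            raise ConfigurationError("manifests must be given with array data")
        if pit_index is None:
            pit_index = np.zeros(len(Y), dtype=int)
    J = int(pit_index.max()) + 1 if len(pit_index) else 1
    model = _Model(spec, tuple(manifests), pit_index, J)
    chains = [
        _run_chain(Y, model, spec, cfg, cfg.base_seed + c, fixed, monitor_alpha)
        for c in range(cfg.chains)
    ]
    names = parameter_names(model, monitor_alpha, pit_ids)
    return PosteriorDraws(draws=np.stack(chains), names=names)


def summarize_effects(
    draws: PosteriorDraws, spec: SemSpec | None = None
) -> pd.DataFrame:
    """Per-path median effect size with equal-tailed 95% credible interval.

    Chains are pooled; the median is the effect size (ES) and the 2.5% and
    97.5% quantiles bound the credible interval.
    """
    spec = spec or SemSpec.default()
    rows = []
    for s, d in spec.paths:
        name = f"gamma[{s}->{d}]"
        try:
            x = draws.pooled(name)
        except KeyError:
            raise KeyError(f"path {s}->{d} not present in draws") from None
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append({"path": f"{s}->{d}", "median": med,
                     "lower": lo, "upper": hi})
    return pd.DataFrame(rows)
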