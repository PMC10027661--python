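"""MCMC convergence diagnostics: split-chain R-hat, autocorrelation ESS.

The potential scale reduction factor is the classic Gelman-Rubin statistic
computed on split chains (each chain halved), comparing between- and
within-sequence variances.  The effective sample size uses the
initial-positive-sequence autocorrelation estimator (Geyer truncation at
the first non-positive paired sum), evaluated per chain and summed.
Thresholds default to the convergence gates R-hat < 1.1 and ESS > 500.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .sem_core import PosteriorDraws


def _chains_array(draws, parameter: str | None = None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise DomainError("parameter name required with PosteriorDraws")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
    if x.ndim != 2:
        raise DomainError("draws must be a (chains, iterations) array")
    return x


def _split(x: np.ndarray) -> np.ndarray:
    """Halve each chain; drop the final draw of odd-length chains."""
    c, n = x.shape
    h = n // 2
    return x[:, : 2 * h].reshape(c * 2, h)


def psrf(draws, parameter: str | None = None) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Approximately 1 for well-mixed stationary chains; values above ~1.1
    indicate that the chains have not converged to a common distribution.
    """
    x = _chains_array(draws, parameter)
    if x.shape[1] < 4:
        raise InsufficientDataError("psrf needs at least 4 draws per chain")
    seqs = _split(x)
    m, h = seqs.shape
    W = float(np.mean(np.var(seqs, axis=1, ddof=1)))
    B = h * float(np.var(np.mean(seqs, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_hat = (h - 1) / h * W + B / h
    return float(np.sqrt(var_hat / W))


def _ess_one_chain(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS of one chain."""
    n = len(x)
    v = np.var(x)
    if v == 0:
        return float(n)
    xc = x - x.mean()
    # autocovariance via FFT
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sum paired autocorrelations until the pair sum goes
    # non-positive
    tau = -1.0
    k = 0
    while 2 * k + 1 < n:
        pair = rho[2 * k] + rho[2 * k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 1
    tau = max(tau, 1.0)
    return min(n / tau, float(n))


def ess_info(draws, parameter: str | None = None) -> tuple[float, bool]:
    """(effective sample size summed over chains, degenerate flag).

    A zero-variance (constant) parameter is flagged degenerate and reports
    the total draw count.
    """
    x = _chains_array(draws, parameter)
    c, n = x.shape
    if c * n < 100:
        raise InsufficientDataError("ess needs at least 100 total draws")
    if np.all(np.var(x, axis=1) == 0):
        return float(c * n), True
    return float(sum(_ess_one_chain(x[i]) for i in range(c))), False


def ess(draws, parameter: str | None = None) -> float:
    """Effective sample size (autocorrelation-based, summed over chains)."""
    return ess_info(draws, parameter)[0]


def thin(draws: PosteriorDraws, k: int) -> PosteriorDraws:
    """Retain every k-th draw (indices 0, k, 2k, ...) per chain."""
    if k < 1:
        raise DomainError("thinning factor must be >= 1")
    return PosteriorDraws(draws=draws.draws[:, ::k, :], names=draws.names)


@dataclass
class ConvergenceReport:
    """Per-parameter diagnostics against the convergence gates."""

    table: pd.DataFrame
    rhat_limit: float
    ess_floor: float
    overall_pass: bool

    @property
    def failing(self) -> list[str]:
        bad = self.table[~self.table["pass"]]
        return list(bad["parameter"])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def convergence_report(
    draws: PosteriorDraws,
    rhat_limit: float = 1.1,
    ess_floor: float = 500.0,
    parameters: list[str] | None = None,
) -> ConvergenceReport:
    """Diagnose every monitored parameter and apply the pass gates.

    The overall pass flag requires R-hat < ``rhat_limit`` and ESS >
    ``ess_floor`` for all (non-degenerate) parameters.
    """
    params = parameters if parameters else list(draws.names)
    rows = []
    for name in params:
        x = draws.get(name)
        r = psrf(x)
        e, degenerate = ess_info(x)
        ok = bool(degenerate or (r < rhat_limit and e > ess_floor))
        rows.append({"parameter": name, "rhat": r, "ess": e,
                     "degenerate": degenerate, "pass": ok})
    table = pd.DataFrame(rows)
    return ConvergenceReport(
        table=table,
        rhat_limit=rhat_limit,
        ess_floor=ess_floor,
        overall_pass=bool(table["pass"].all()),
    )
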