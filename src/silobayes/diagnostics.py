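"""Geweke convergence diagnostic for single MCMC chains.

The statistic compares the mean of an early window (default the first 10% of
draws) against a late window (default the last 50%):

    z = (m_A - m_B) / sqrt(S_A(0)/n_A + S_B(0)/n_B)

where S(0) is the spectral density at frequency zero of each window,
estimated by an autoregressive fit with AIC order selection, so
autocorrelation within the windows is accounted for.  Under convergence z is
approximately standard normal; |z| > 1.96 flags a parameter at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.ar_model import AutoReg, ar_select_order

from .errors import DegenerateChainError
from .sampler import ChainResult


@dataclass
class GewekeReport:
    """Per-parameter z scores plus the window fractions used."""

    z: dict[str, float]
    window_first: float = 0.1
    window_last: float = 0.5

    def flagged(self, threshold: float = 1.96) -> list[str]:
        return [k for k, v in self.z.items() if abs(v) > threshold]

    @property
    def max_abs_z(self) -> float:
        return max(abs(v) for v in self.z.values())


def spectral_density_at_zero(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit.

    S(0) = sigma2_resid / (1 - sum(phi))^2.  Near-unit-root fits (coefficient
    sum >= 0.999, e.g. on deterministic trends) make this ratio numerically
    meaningless, so the plain window variance is returned instead; that keeps
    the statistic finite and trends detectable.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    var = float(np.var(x))
    if var == 0.0:
        raise DegenerateChainError("window has zero variance")
    if max_order is None:
        max_order = int(min(20, np.floor(10 * np.log10(n))))
    try:
        sel = ar_select_order(x, maxlag=max_order, ic="aic", trend="c", old_names=False)
        lags = sel.ar_lags or []
    except Exception:
        lags = []
    if not lags:
        return var
    fit = AutoReg(x, lags=lags, trend="c", old_names=False).fit()
    phi_sum = float(np.sum(fit.params[1:]))
    if phi_sum >= 0.999:
        return var
    return float(fit.sigma2 / (1.0 - phi_sum) ** 2)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z score for one scalar chain."""
    chain = np.asarray(chain, dtype=float).ravel()
    n = chain.size
    if n < 100:
        raise DegenerateChainError(f"chain too short for the diagnostic (n={n} < 100)")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("window fractions must lie in (0,1) and not overlap")
    n_a = int(np.floor(first * n))
    n_b = int(np.floor(last * n))
    a, b = chain[:n_a], chain[n - n_b:]
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise DegenerateChainError("constant chain window; diagnostic undefined")
    s_a = spectral_density_at_zero(a)
    s_b = spectral_density_at_zero(b)
    return float((a.mean() - b.mean()) / np.sqrt(s_a / n_a + s_b / n_b))


def geweke_report(result: ChainResult, first: float = 0.1, last: float = 0.5) -> GewekeReport:
    """z score for every scalar parameter chain of a fitted model.

    Constant chains (e.g. an effect pinned at zero in a degenerate design)
    are reported as z = 0 with a ``*degenerate`` marker suffix rather than
    failing the whole report.
    """
    z: dict[str, float] = {}
    for name, chain in result.scalar_chains().items():
        try:
            z[name] = geweke_z(chain, first=first, last=last)
        except DegenerateChainError:
            z[name + "*degenerate"] = 0.0
    return GewekeReport(z=z, window_first=first, window_last=last)
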