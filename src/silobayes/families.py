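"""Observation families: densities, deviances and links.

Four families are supported for the count vector y given the latent vector l:

* ``poisson`` — y_i ~ Poisson(lambda_i = exp(l_i)), the log link.
* ``zip`` — zero-inflated Poisson: a structural zero with probability pi,
  otherwise a Poisson draw (which may itself be zero).
* ``hurdle`` — zero-altered Poisson: zero with probability pi, otherwise a
  zero-truncated Poisson.  ``zap`` is accepted as an alias since the
  zero-altered and hurdle formulations coincide.
* ``normal`` — y_i ~ N(l_i, sigma2) on the raw count scale, identity link;
  the baseline Gaussian fit.

pi is a single scalar per model.  All computations are done in log space and
remain stable for rates spanning many orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import SpecError

FAMILIES = ("normal", "poisson", "zip", "hurdle")
FAMILY_ALIASES = {"zap": "hurdle"}
ZERO_MODIFIED = ("zip", "hurdle")

# prior defaults: flat Gaussian for b; sigma2_k ~ IG(alpha/2, alpha*beta/2)
# with alpha = beta = 0.001 for the u-blocks, and alpha_e = 0.001,
# beta_e = 1e8 for the error variance.
DEFAULT_PRIOR_VAR_B = 1e8
DEFAULT_BLOCK_HYPER = (0.001, 0.001)
DEFAULT_ERROR_HYPER = (0.001, 1e8)


def canonical_family(name: str) -> str:
    fam = FAMILY_ALIASES.get(name, name)
    if fam not in FAMILIES:
        raise SpecError(
            f"unknown family {name!r}; allowed: {FAMILIES + tuple(FAMILY_ALIASES)}"
        )
    return fam


@dataclass
class ModelSpec:
    """Family, link and prior hyperparameters of one candidate model."""

    family: str = "poisson"
    include_blocks: tuple[str, ...] = ("u1", "u2", "u3", "u4")
    prior_var_b: float = DEFAULT_PRIOR_VAR_B
    hyper: dict[str, tuple[float, float]] = field(default_factory=dict)
    pi_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.family = canonical_family(self.family)
        self.include_blocks = tuple(self.include_blocks)
        full = dict.fromkeys(("u1", "u2", "u3", "u4"), DEFAULT_BLOCK_HYPER)
        full["e"] = DEFAULT_ERROR_HYPER
        full.update(self.hyper)
        self.hyper = full
        for k, (a, b) in self.hyper.items():
            if a <= 0 or b <= 0:
                raise SpecError(f"hyperparameters for {k} must be positive, got {(a, b)}")
        if self.prior_var_b <= 0:
            raise SpecError("prior_var_b must be positive")
        if min(self.pi_prior) <= 0:
            raise SpecError("pi_prior Beta parameters must be positive")

    @property
    def link(self) -> str:
        return "identity" if self.family == "normal" else "log"


def _check_pi(family: str, pi: float | None) -> float | None:
    if family in ZERO_MODIFIED:
        if pi is None:
            raise SpecError(f"family {family!r} requires a zero probability pi")
        if not 0.0 <= pi <= 1.0:
            raise ValueError(f"pi must lie in [0, 1], got {pi}")
        return float(pi)
    if pi is not None:
        raise SpecError(f"family {family!r} takes no zero probability (pi supplied)")
    return None


def _log_pois(y: np.ndarray, l: np.ndarray) -> np.ndarray:
    # log Poisson pmf with lambda = exp(l):  y*l - exp(l) - log(y!)
    return y * l - np.exp(l) - gammaln(y + 1.0)


def loglik_site(
    family: str,
    y: np.ndarray,
    l: np.ndarray,
    pi: float | None = None,
    sigma2: float | None = None,
) -> np.ndarray:
    """Per-observation log-likelihood contributions.

    For ``normal`` the observation variance ``sigma2`` must be supplied (it is
    a sampled parameter, not a fixed constant).
    """
    family = canonical_family(family)
    y = np.asarray(y, dtype=float)
    l = np.asarray(l, dtype=float)
    if y.shape != l.shape:
        raise ValueError(f"y and l shapes differ: {y.shape} vs {l.shape}")
    pi = _check_pi(family, pi)

    if family == "normal":
        if sigma2 is None or sigma2 <= 0:
            raise SpecError("normal family requires a positive observation variance sigma2")
        return -0.5 * (np.log(2 * np.pi * sigma2) + (y - l) ** 2 / sigma2)

    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count families require non-negative integer y")
    lp = _log_pois(y, l)
    if family == "poisson":
        return lp

    zero = y == 0
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    if family == "zip":
        out = log_1mpi + lp
        if np.any(zero):
            # log( pi + (1-pi) e^{-lambda} ) via logaddexp for stability
            out = np.where(zero, np.logaddexp(log_pi, log_1mpi - np.exp(l)), out)
        return out
    # hurdle: P(0) = pi; P(y>0) = (1-pi) Pois(y|lambda) / (1 - e^{-lambda})
    lam = np.exp(l)
    # log(1 - e^{-lam}) computed stably for small lam
    log_norm = np.log(-np.expm1(-lam))
    return np.where(zero, log_pi, log_1mpi + lp - log_norm)


def loglik(
    family: str,
    y: np.ndarray,
    l: np.ndarray,
    pi: float | None = None,
    sigma2: float | None = None,
) -> float:
    """Total log-likelihood sum_i log p(y_i | l_i, ...)."""
    return float(np.sum(loglik_site(family, y, l, pi=pi, sigma2=sigma2)))


def deviance(
    family: str,
    y: np.ndarray,
    l: np.ndarray,
    pi: float | None = None,
    sigma2: float | None = None,
) -> float:
    """Deviance, defined throughout the package as -2 * log-likelihood."""
    return -2.0 * loglik(family, y, l, pi=pi, sigma2=sigma2)
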