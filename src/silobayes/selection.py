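"""DIC computation and smallest-DIC model selection.

Two deviance conditionings are provided.  The default, ``marginal``,
integrates the latent Gaussian residual e out of the likelihood by
Gauss-Hermite quadrature, so the deviance is a function of the systematic
mean mu = X b + sum Z_k u_k, the latent variance sigma2_e and (for
zero-modified families) pi:

    p(y_i | mu_i, sigma2_e, pi) = Integral family(y_i | l) N(l | mu_i, sigma2_e) dl

Dbar averages D = -2 log p(y | .) over retained draws, Dhat plugs in the
posterior means of (mu, sigma2_e, pi), pD = Dbar - Dhat and DIC = Dbar + pD.
Marginalizing e is what makes DIC discriminate between observation families:
the alternative ``conditional`` variant (deviance as a function of the
latent field l itself) lets any count family absorb lack of fit into l and
is retained only for diagnostics.

Smaller DIC wins; ties break toward fewer random-effect blocks, then
lexicographic family order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import SpecError
from .families import deviance, loglik_site, ZERO_MODIFIED
from .io import CountTable
from .sampler import ChainResult

DIC_VARIANTS = ("marginal", "conditional")

# marginality-respecting candidate block structures: u4 only with u2 and u3,
# u2/u3 only with u1
STRUCTURE_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("u1",),
    ("u1", "u2"),
    ("u1", "u3"),
    ("u1", "u2", "u3"),
    ("u1", "u2", "u3", "u4"),
)


@dataclass
class DicReport:
    dbar: float
    dhat: float
    family: str
    include_blocks: tuple[str, ...] = ()
    variant: str = "marginal"
    pd: float = field(init=False)
    dic: float = field(init=False)

    def __post_init__(self) -> None:
        self.pd = self.dbar - self.dhat
        self.dic = self.dbar + self.pd


def marginal_deviance(
    family: str,
    y: np.ndarray,
    mu: np.ndarray,
    sigma2_e: float,
    pi: float | None = None,
    n_nodes: int = 31,
) -> float:
    """Deviance with the latent residual integrated out by Gauss-Hermite.

    For the normal family sigma2_e already is the observation variance, so
    no quadrature is needed.
    """
    if family == "normal":
        return deviance(family, y, mu, sigma2=sigma2_e)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # l = mu + sqrt(2 sigma2) x  at physicists' nodes x
    l = mu[None, :] + np.sqrt(2.0 * sigma2_e) * nodes[:, None]
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll = loglik_site(family, np.broadcast_to(y, l.shape), l, pi=pi)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    log_p = logsumexp(ll + np.log(weights)[:, None], axis=0) - 0.5 * np.log(np.pi)
    return float(-2.0 * np.sum(log_p))


def compute_dic(
    result: ChainResult,
    table: CountTable | None = None,
    variant: str = "marginal",
    n_nodes: int = 31,
) -> DicReport:
    """DIC of a fitted chain (default: latent-residual-marginalized deviance).

    ``table`` is optional cross-validation: when given, its digest must match
    the one recorded in the chain, guarding against scoring a chain on the
    wrong dataset.
    """
    if variant not in DIC_VARIANTS:
        raise SpecError(f"DIC variant must be one of {DIC_VARIANTS}, got {variant!r}")
    if table is not None:
        from .sampler import _digest

        if result.dataset_digest and _digest(table) != result.dataset_digest:
            raise SpecError("count table does not match the dataset the chain was fitted on")
    if result.n_draws < 100:
        raise SpecError(f"need >= 100 retained draws for DIC, have {result.n_draws}")

    y = result.y
    family = result.family
    pi_draws = result.draws.get("pi")
    R = result.n_draws

    if variant == "marginal":
        mu_draws = result.draws["mu"]
        s2 = result.sigma2("e")
        devs = np.array(
            [
                marginal_deviance(
                    family,
                    y,
                    mu_draws[i],
                    float(s2[i]),
                    pi=None if pi_draws is None else float(pi_draws[i]),
                    n_nodes=n_nodes,
                )
                for i in range(R)
            ]
        )
        dhat = marginal_deviance(
            family,
            y,
            mu_draws.mean(axis=0),
            float(s2.mean()),
            pi=None if pi_draws is None else float(pi_draws.mean()),
            n_nodes=n_nodes,
        )
    else:
        l_draws = result.draws["l"]
        if family == "normal":
            s2 = result.sigma2("e")
            devs = np.array(
                [deviance(family, y, l_draws[i], sigma2=float(s2[i])) for i in range(R)]
            )
            dhat = deviance(family, y, l_draws.mean(axis=0), sigma2=float(s2.mean()))
        elif family in ZERO_MODIFIED:
            devs = np.array(
                [deviance(family, y, l_draws[i], pi=float(pi_draws[i])) for i in range(R)]
            )
            dhat = deviance(family, y, l_draws.mean(axis=0), pi=float(pi_draws.mean()))
        else:
            devs = np.array([deviance(family, y, l_draws[i]) for i in range(R)])
            dhat = deviance(family, y, l_draws.mean(axis=0))
    return DicReport(
        dbar=float(devs.mean()),
        dhat=float(dhat),
        family=family,
        include_blocks=tuple(result.include_blocks),
        variant=variant,
    )


def select_model(reports: list[DicReport]) -> tuple[DicReport, list[DicReport]]:
    """Smallest-DIC winner plus the full ranking.

    Ties break toward fewer included random-effect blocks, then toward
    lexicographically earlier family names.
    """
    if not reports:
        raise ValueError("no DIC reports to rank")
    ranked = sorted(reports, key=lambda r: (r.dic, len(r.include_blocks), r.family))
    return ranked[0], ranked
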