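"""Metropolis-within-Gibbs sampler for the latent-Gaussian count model.

The joint model is

    y_i ~ family(exp(l_i), pi)          (identity link for the normal family)
    l | b, u, sigma2_e ~ N(X b + sum_k Z_k u_k, I sigma2_e)
    b ~ N(0, I * prior_var_b),   u_k ~ N(0, I sigma2_k)
    sigma2_k ~ IG(alpha_k/2, alpha_k beta_k/2),  similarly sigma2_e
    pi ~ Beta(a, b)                      (zip / hurdle only)

All conditionals are conjugate (Gaussian blocks, inverse-gamma variances,
Beta zero probability) except the latent sites l_i under a count family,
which get a site-wise random-walk Metropolis step with optional
Robbins-Monro adaptation of the proposal scale during burn-in (frozen
afterwards, so the invariant distribution is untouched).  For the zip family
the latent update targets the z-marginalized mixture likelihood; the
structural-zero indicators are refreshed afterwards only to update pi, which
is a valid partially collapsed scheme.

For the normal family the latent vector is the observation itself
(y = X b + sum Z_k u_k + e), so the whole sampler is a conjugate Gibbs
scheme; the stored "l" draws are then the fitted means X b + sum Z_k u_k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import linalg

from .design import FactorialDesign, build_design
from .errors import ChainError, SpecError
from .families import ModelSpec, ZERO_MODIFIED, loglik_site
from .io import CountTable

STUDY_PROTOCOL = dict(iterations=2_000_000, burn_in=100_000, thin=10)


@dataclass
class SamplerConfig:
    """MCMC run lengths and proposal settings.

    Defaults follow the study protocol: 2,000,000 sweeps, the first 100,000
    discarded as burn-in, one retained draw per 10 (thin).  Desk-scale runs
    override these; retained draws = floor((iterations - burn_in) / thin).
    """

    iterations: int = STUDY_PROTOCOL["iterations"]
    burn_in: int = STUDY_PROTOCOL["burn_in"]
    thin: int = STUDY_PROTOCOL["thin"]
    seed: int = 0
    latent_step: float | str = "adaptive"
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.latent_step != "adaptive" and float(self.latent_step) <= 0:
            raise ValueError("latent_step must be positive or 'adaptive'")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ChainResult:
    """Retained posterior draws plus provenance."""

    draws: dict[str, np.ndarray]
    sigma2_labels: list[str]
    family: str
    include_blocks: tuple[str, ...]
    config: SamplerConfig
    x_labels: list[str]
    z_labels: dict[str, list[tuple]]
    periods: list[int]
    inoculants: list[str]
    taxa: list[str]
    y: np.ndarray
    acceptance_rate: float
    dataset_digest: str = ""

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def sigma2(self, label: str) -> np.ndarray:
        return self.draws["sigma2"][:, self.sigma2_labels.index(label)]

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Every scalar parameter chain, for convergence diagnostics."""
        out = {f"b[{lab}]": self.draws["b"][:, j] for j, lab in enumerate(self.x_labels)}
        for j, lab in enumerate(self.sigma2_labels):
            out[f"sigma2[{lab}]"] = self.draws["sigma2"][:, j]
        if "pi" in self.draws:
            out["pi"] = self.draws["pi"]
        return out


def update_variance(u_block: np.ndarray, hyper: tuple[float, float], rng: np.random.Generator) -> float:
    """One draw of sigma2 | u from its inverse-gamma full conditional.

    The prior IG(alpha/2, alpha*beta/2) combines with q = len(u) Gaussian
    effects into IG(alpha/2 + q/2, alpha*beta/2 + u'u/2); q = 0 returns a
    prior draw.
    """
    alpha, beta = hyper
    if alpha <= 0 or beta <= 0:
        raise ValueError("hyperparameters must be positive")
    u = np.asarray(u_block, dtype=float)
    shape = alpha / 2.0 + u.size / 2.0
    rate = alpha * beta / 2.0 + float(u @ u) / 2.0
    return float(rate / rng.gamma(shape))


def update_gaussian_block(
    resid: np.ndarray,
    Z: np.ndarray,
    sigma2_block: float,
    sigma2_e: float,
    rng: np.random.Generator,
    name: str = "block",
) -> np.ndarray:
    """Exact draw of a Gaussian effect block from its full conditional.

    Target: N(V Z'resid / sigma2_e, V) with V = (Z'Z/sigma2_e + I/sigma2_block)^-1,
    where ``resid`` is the latent vector minus every other systematic term.
    Computed through a Cholesky factorization of the precision, never an
    explicit inverse.
    """
    if sigma2_block <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    q = Z.shape[1]
    prec = Z.T @ Z / sigma2_e + np.eye(q) / sigma2_block
    try:
        L = linalg.cholesky(prec, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ChainError(f"singular full-conditional precision for {name}") from exc
    rhs = Z.T @ resid / sigma2_e
    mean = linalg.cho_solve((L, True), rhs)
    noise = linalg.solve_triangular(L, rng.standard_normal(q), lower=True, trans="T")
    return mean + noise


def _site_loglik(family: str, y: np.ndarray, l: np.ndarray, pi: float | None) -> np.ndarray:
    """Per-site count-family log-likelihood, up to terms constant in l.

    Agrees with :func:`silobayes.families.loglik_site` after adding
    l-independent constants, which cancel in Metropolis ratios.
    """
    lam = np.exp(l)
    if family == "poisson":
        return y * l - lam
    if family == "zip":
        out = y * l - lam
        zero = y == 0
        if np.any(zero):
            with np.errstate(divide="ignore"):
                out = np.where(
                    zero, np.logaddexp(np.log(pi), np.log1p(-pi) - lam), out
                )
        return out
    if family == "hurdle":
        zero = y == 0
        out = y * l - lam - np.log(-np.expm1(-lam))
        return np.where(zero, 0.0, out)
    return loglik_site(family, y, l, pi=pi)


def update_latent(
    y: np.ndarray,
    l: np.ndarray,
    mu: np.ndarray,
    sigma2_e: float,
    family: str,
    pi: float | None,
    step: float | np.ndarray,
    rng: np.random.Generator,
    likelihood_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Site-wise random-walk Metropolis update of the latent vector.

    Each site targets p(l_i) proportional to family(y_i | l_i, pi) *
    N(l_i | mu_i, sigma2_e); sites are conditionally independent, so the
    whole vector is proposed and accepted element-wise.  Returns the new
    latent vector and the per-site acceptance flags.  ``likelihood_weight``
    tempers the observation term (0 reduces the target to the Gaussian
    prior; used by validation checks).
    """
    if not np.all(np.isfinite(mu)):
        raise ChainError("non-finite latent conditional mean")
    prop = l + step * rng.standard_normal(l.shape)
    log_ratio = ((l + prop) / 2.0 - mu) * (l - prop) / sigma2_e  # Gaussian prior part
    if likelihood_weight != 0.0:
        log_ratio = log_ratio + likelihood_weight * (
            _site_loglik(family, y, prop, pi) - _site_loglik(family, y, l, pi)
        )
    accept = np.log(rng.random(l.shape)) < log_ratio
    return np.where(accept, prop, l), accept


def update_zero_layer(
    y: np.ndarray,
    l: np.ndarray,
    pi: float | None,
    pi_prior: tuple[float, float],
    family: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, float]:
    """Refresh structural-zero indicators (zip) and the zero probability pi.

    zip: z_i | rest ~ Bernoulli(pi / (pi + (1-pi) e^{-lambda_i})) at zero
    observations (z_i = 0 whenever y_i > 0), then pi | z ~ Beta(a + sum z,
    b + n - sum z); ``pi`` is the current value entering the z draw.
    hurdle: zeros are entirely structural, so pi | y ~ Beta(a + #zeros,
    b + #positives) directly and z is None.
    """
    if family not in ZERO_MODIFIED:
        raise SpecError(f"zero layer only applies to {ZERO_MODIFIED}, not {family!r}")
    a, b = pi_prior
    y = np.asarray(y)
    n = y.size
    if family == "hurdle":
        n0 = int(np.sum(y == 0))
        return None, float(rng.beta(a + n0, b + n - n0))
    if pi is None or not 0.0 <= pi <= 1.0:
        raise ValueError(f"zip zero layer needs a current pi in [0, 1], got {pi!r}")
    zero = y == 0
    z = np.zeros(n, dtype=np.int8)
    if np.any(zero):
        lam = np.exp(np.asarray(l)[zero])
        p1 = pi / (pi + (1.0 - pi) * np.exp(-lam))
        z[zero] = rng.random(p1.size) < p1
    s = int(z.sum())
    return z, float(rng.beta(a + s, b + n - s))


def _digest(table: CountTable) -> str:
    import hashlib

    h = hashlib.sha256()
    for t, s, c in sorted(table.records):
        h.update(f"{t}\t{s}\t{c}\n".encode())
    for s in sorted(table.metadata):
        m = table.metadata[s]
        h.update(f"{m.sample_id}\t{m.grain}\t{m.inoculant}\t{m.period_days}\t{m.replicate}\n".encode())
    return h.hexdigest()[:16]


def run_chain(
    table: CountTable,
    spec: ModelSpec,
    config: SamplerConfig,
    design: FactorialDesign | None = None,
) -> ChainResult:
    """Run the full Metropolis-within-Gibbs cycle and return retained draws.

    Sweep order: latent sites -> b -> each included u-block -> variances ->
    zero layer.  Identical (table, spec, config) reproduce identical draws.
    """
    if design is None:
        design = build_design(table, include_blocks=spec.include_blocks)
    y = design.y
    n = design.n
    family = spec.family
    count_family = family != "normal"
    if count_family and (np.any(y < 0) or np.any(y != np.floor(y))):
        raise SpecError(f"family {family!r} requires non-negative integer counts")
    if count_family and np.all(y == 0):
        import warnings

        warnings.warn("all counts are zero; posterior rates concentrate near 0", stacklevel=2)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    blocks = tuple(b for b in spec.include_blocks if b in design.z_index)

    X = design.X
    XtX = X.T @ X
    p = X.shape[1]
    z_idx = {k: design.z_index[k] for k in blocks}
    z_q = {k: len(design.z_labels[k]) for k in blocks}
    z_counts = {k: np.bincount(z_idx[k], minlength=z_q[k]).astype(float) for k in blocks}

    # initialization: quasi-likelihood intercept, zero effects, unit variances
    b = np.zeros(p)
    if count_family:
        b[0] = np.log(np.mean(y) + 0.5)
        l = np.log(y + 0.5)
    else:
        b[0] = np.mean(y)
        l = y.astype(float).copy()
    u = {k: np.zeros(z_q[k]) for k in blocks}
    sigma2 = {k: 1.0 for k in blocks}
    sigma2_e = 1.0
    pi = None
    if family in ZERO_MODIFIED:
        pi = float(np.clip(np.mean(y == 0), 0.02, 0.98))

    adaptive = config.latent_step == "adaptive"
    log_step = np.full(n, np.log(0.5)) if adaptive else np.log(float(config.latent_step)) * np.ones(n)

    retained = config.retained
    draws: dict[str, np.ndarray] = {
        "b": np.empty((retained, p)),
        "l": np.empty((retained, n)),
        "mu": np.empty((retained, n)),
    }
    for k in blocks:
        draws[k] = np.empty((retained, z_q[k]))
    sigma2_labels = list(blocks) + ["e"]
    draws["sigma2"] = np.empty((retained, len(sigma2_labels)))
    if pi is not None:
        draws["pi"] = np.empty(retained)

    def systematic() -> np.ndarray:
        out = X @ b
        for k in blocks:
            out = out + u[k][z_idx[k]]
        return out

    accept_sum = 0.0
    accept_n = 0
    kept = 0
    for sweep in range(config.iterations):
        if count_family:
            mu = systematic()
            l, acc = update_latent(y, l, mu, sigma2_e, family, pi, np.exp(log_step), rng)
            if adaptive and sweep < config.burn_in:
                gamma = (sweep + 1.0) ** -0.6
                log_step += gamma * (acc.astype(float) - config.target_accept)
            if sweep >= config.burn_in:
                accept_sum += float(np.mean(acc))
                accept_n += 1
        # b | rest : Gaussian with flat prior variance
        rest = l - sum((u[k][z_idx[k]] for k in blocks), np.zeros(n))
        prec = XtX / sigma2_e + np.eye(p) / spec.prior_var_b
        L = np.linalg.cholesky(prec)
        mean = linalg.cho_solve((L, True), X.T @ rest / sigma2_e)
        b = mean + linalg.solve_triangular(L, rng.standard_normal(p), lower=True, trans="T")
        # u_k | rest : diagonal Gaussian (incidence blocks have diagonal Z'Z)
        xb = X @ b
        for k in blocks:
            resid = l - xb
            for j in blocks:
                if j != k:
                    resid = resid - u[j][z_idx[j]]
            ztr = np.bincount(z_idx[k], weights=resid, minlength=z_q[k])
            v = 1.0 / (z_counts[k] / sigma2_e + 1.0 / sigma2[k])
            u[k] = v * ztr / sigma2_e + np.sqrt(v) * rng.standard_normal(z_q[k])
        # variances
        for k in blocks:
            sigma2[k] = update_variance(u[k], spec.hyper[k], rng)
        e = l - systematic()
        alpha_e, beta_e = spec.hyper["e"]
        sigma2_e = float(
            (alpha_e * beta_e / 2.0 + e @ e / 2.0) / rng.gamma(alpha_e / 2.0 + n / 2.0)
        )
        # zero layer
        if family in ZERO_MODIFIED:
            _, pi = update_zero_layer(y, l, pi, spec.pi_prior, family, rng)

        if not (np.isfinite(l).all() and np.isfinite(b).all() and np.isfinite(sigma2_e)):
            raise ChainError(f"non-finite sampler state at sweep {sweep}")

        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == config.thin - 1:
            if kept < retained:
                fitted = systematic()
                draws["b"][kept] = b
                draws["l"][kept] = l if count_family else fitted
                draws["mu"][kept] = fitted
                for k in blocks:
                    draws[k][kept] = u[k]
                draws["sigma2"][kept] = [sigma2[k] for k in blocks] + [sigma2_e]
                if pi is not None:
                    draws["pi"][kept] = pi
                kept += 1

    for key in draws:
        draws[key] = draws[key][:kept]

    return ChainResult(
        draws=draws,
        sigma2_labels=sigma2_labels,
        family=family,
        include_blocks=blocks,
        config=config,
        x_labels=list(design.x_labels),
        z_labels={k: list(design.z_labels[k]) for k in blocks},
        periods=list(design.periods),
        inoculants=list(design.inoculants),
        taxa=list(design.taxa),
        y=y.copy(),
        acceptance_rate=float(accept_sum / accept_n) if accept_n else 1.0,
        dataset_digest=_digest(table),
    )


def save_chain(result: ChainResult, directory: str | Path) -> None:
    """Serialize a chain to a directory: one CSV per draw block + meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for key, arr in result.draws.items():
        np.savetxt(directory / f"draws_{key}.csv", np.atleast_2d(arr.T).T, delimiter=",")
    meta = {
        "family": result.family,
        "include_blocks": list(result.include_blocks),
        "sigma2_labels": result.sigma2_labels,
        "config": asdict(result.config),
        "x_labels": result.x_labels,
        "z_labels": {k: [list(map(str, t)) for t in v] for k, v in result.z_labels.items()},
        "periods": result.periods,
        "inoculants": result.inoculants,
        "taxa": result.taxa,
        "y": result.y.tolist(),
        "acceptance_rate": result.acceptance_rate,
        "dataset_digest": result.dataset_digest,
        "draw_keys": list(result.draws),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_chain(directory: str | Path) -> ChainResult:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    draws = {}
    for key in meta["draw_keys"]:
        arr = np.loadtxt(directory / f"draws_{key}.csv", delimiter=",", ndmin=2)
        draws[key] = arr[:, 0] if key == "pi" else arr
    z_labels = {}
    for k, labs in meta["z_labels"].items():
        z_labels[k] = [tuple(int(x) if x.isdigit() else x for x in t) for t in labs]
    return ChainResult(
        draws=draws,
        sigma2_labels=meta["sigma2_labels"],
        family=meta["family"],
        include_blocks=tuple(meta["include_blocks"]),
        config=SamplerConfig(**meta["config"]),
        x_labels=meta["x_labels"],
        z_labels=z_labels,
        periods=meta["periods"],
        inoculants=meta["inoculants"],
        taxa=meta["taxa"],
        y=np.asarray(meta["y"], dtype=float),
        acceptance_rate=meta["acceptance_rate"],
        dataset_digest=meta.get("dataset_digest", ""),
    )
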