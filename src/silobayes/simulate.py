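"""Synthetic factorial OTU-count generator with known ground truth.

Datasets follow exactly the generative structure the abundance model assumes:
a latent Gaussian linear predictor l = X b + sum_k Z_k u_k + e over a
taxon x inoculant x period x replicate grid, with u_k ~ N(0, sigma2_k I),
e ~ N(0, sigma2_e I), and counts drawn from a Poisson-family observation
model on lambda = exp(l).  Zero modification is a structural-zero mixture
applied on top of the Poisson draw for ``zip``, and a zero-vs-truncated
two-part process for ``hurdle``.

One root seed drives everything; per-stage generators are spawned
deterministically from it so identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .design import build_design, ALL_BLOCKS
from .errors import SpecError
from .families import canonical_family
from .io import CountTable, SampleMeta, INOCULANT_LEVELS, PERIOD_LEVELS

SCENARIOS = ("corn-like", "sorghum-like", "zero-heavy", "null")


@dataclass
class TruthRecord:
    """Ground-truth parameters behind one simulated dataset."""

    b_true: np.ndarray
    sigma2_true: dict[str, float]
    family: str = "poisson"
    pi_zero: float = 0.0
    seed: int = 0
    u_true: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.family = canonical_family(self.family)
        self.b_true = np.asarray(self.b_true, dtype=float)
        for k, v in self.sigma2_true.items():
            if v < 0:
                raise ValueError(f"variance for {k} must be >= 0, got {v}")
        if not 0.0 <= self.pi_zero <= 1.0:
            raise ValueError(f"pi_zero must lie in [0, 1], got {self.pi_zero}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["b_true"] = self.b_true.tolist()
        d["u_true"] = {k: v.tolist() for k, v in self.u_true.items()}
        return d


def _grid_metadata(
    grain: str,
    inoculants: tuple[str, ...],
    periods: tuple[int, ...],
    n_replicates: int,
) -> dict[str, SampleMeta]:
    meta: dict[str, SampleMeta] = {}
    for i in inoculants:
        for p in periods:
            for r in range(1, n_replicates + 1):
                sid = f"{grain}_{i}_d{p}_r{r}"
                meta[sid] = SampleMeta(sid, grain, i, p, r)
    return meta


def simulate_dataset(
    n_taxa: int,
    n_replicates: int,
    truth: TruthRecord,
    inoculants: tuple[str, ...] = INOCULANT_LEVELS,
    periods: tuple[int, ...] = PERIOD_LEVELS,
    grain: str = "corn",
) -> tuple[CountTable, TruthRecord]:
    """Simulate a balanced factorial count table under ``truth``.

    The returned TruthRecord is a copy of ``truth`` with the drawn random
    effects filled into ``u_true`` (effects for blocks whose variance is 0 or
    absent are zero vectors and omitted).  ``b_true`` must match the fixed
    design: 1 + (P-1) + (I-1) entries under reference coding.
    """
    if n_taxa < 1 or n_replicates < 1:
        raise ValueError("n_taxa and n_replicates must be positive")
    root = np.random.SeedSequence(truth.seed)
    rng_u, rng_e, rng_y, rng_z = (np.random.default_rng(s) for s in root.spawn(4))

    meta = _grid_metadata(grain, tuple(inoculants), tuple(periods), n_replicates)
    taxa = [f"OTU{j + 1:03d}" for j in range(n_taxa)]
    skeleton = CountTable(
        records=[(t, s, 0) for t in taxa for s in meta], metadata=meta
    )
    blocks = tuple(k for k in ALL_BLOCKS if truth.sigma2_true.get(k, 0.0) > 0)
    design = build_design(skeleton, include_blocks=ALL_BLOCKS)

    p_fix = design.X.shape[1]
    if truth.b_true.shape != (p_fix,):
        raise ValueError(
            f"b_true has {truth.b_true.size} entries; design needs {p_fix} "
            f"(intercept + {len(periods) - 1} periods + {len(inoculants) - 1} inoculants)"
        )

    l = design.X @ truth.b_true
    u_true: dict[str, np.ndarray] = {}
    for k in ALL_BLOCKS:
        q = len(design.z_labels[k])
        sd = float(np.sqrt(truth.sigma2_true.get(k, 0.0)))
        u = rng_u.normal(0.0, sd, size=q) if k in blocks else np.zeros(q)
        u_true[k] = u
        l = l + u[design.z_index[k]]
    sigma_e = float(np.sqrt(truth.sigma2_true.get("e", 0.0)))
    l = l + rng_e.normal(0.0, sigma_e, size=design.n)

    lam = np.exp(l)
    family = truth.family
    if family in ("poisson", "zip"):
        y = rng_y.poisson(lam)
        if family == "zip" and truth.pi_zero > 0:
            y = np.where(rng_z.random(design.n) < truth.pi_zero, 0, y)
    elif family == "hurdle":
        # two-part: structural zero w.p. pi, else zero-truncated Poisson via
        # inverse-cdf on the truncated tail
        zero = rng_z.random(design.n) < truth.pi_zero
        u = rng_y.random(design.n)
        from scipy.stats import poisson as _pois

        # P(Y <= y | Y >= 1) inverted: ppf over the rescaled uniform
        p0 = np.exp(-lam)
        y = _pois.ppf(p0 + u * (1.0 - p0), lam).astype(int)
        y = np.maximum(y, 1)
        y[zero] = 0
    elif family == "normal":
        y = np.maximum(np.rint(rng_y.normal(l, 1.0)), 0).astype(int)
    else:  # pragma: no cover
        raise SpecError(f"unknown family {family!r}")

    records = [
        (t, s, int(c)) for (t, s), c in zip(design.rows, np.asarray(y, dtype=int))
    ]
    out_truth = TruthRecord(
        b_true=truth.b_true.copy(),
        sigma2_true=dict(truth.sigma2_true),
        family=family,
        pi_zero=truth.pi_zero,
        seed=truth.seed,
        u_true=u_true,
    )
    return CountTable(records=records, metadata=meta), out_truth


def scenario(name: str, seed: int = 0) -> tuple[CountTable, TruthRecord]:
    """Documented presets sized to the study: 3 inoculants x 6 periods x 3 reps.

    * ``corn-like`` — 6 taxa, moderate taxon heterogeneity (sigma2_1 = 1),
      smaller interaction variances, mild period/inoculant fixed effects
      around a mean abundance near exp(1.6) ~ 5 reads.
    * ``sorghum-like`` — fewer dominant taxa with stronger taxon variance and
      a higher baseline, echoing the lower-evenness sorghum communities.
    * ``zero-heavy`` — corn-like latent structure with structural zeros at
      probability 0.4, for exercising zero-modified model selection.
    * ``null`` — all random-effect variances and non-intercept fixed effects
      zero; the no-signal reference.
    """
    p_fix = 1 + (len(PERIOD_LEVELS) - 1) + (len(INOCULANT_LEVELS) - 1)
    if name == "null":
        b = np.zeros(p_fix)
        b[0] = np.log(5.0)
        truth = TruthRecord(
            b_true=b,
            sigma2_true={"u1": 0.0, "u2": 0.0, "u3": 0.0, "u4": 0.0, "e": 0.0},
            family="poisson",
            seed=seed,
        )
        return simulate_dataset(6, 3, truth)
    if name == "corn-like":
        b = np.concatenate(
            [[1.6], [0.3, 0.2, -0.2, 0.1, -0.1], [-0.2, -0.15]]
        )
        truth = TruthRecord(
            b_true=b,
            sigma2_true={"u1": 1.0, "u2": 0.2, "u3": 0.2, "u4": 0.1, "e": 0.25},
            family="poisson",
            seed=seed,
        )
        return simulate_dataset(6, 3, truth)
    if name == "sorghum-like":
        b = np.concatenate(
            [[2.5], [0.2, 0.1, -0.3, -0.1, 0.1], [0.1, -0.3]]
        )
        truth = TruthRecord(
            b_true=b,
            sigma2_true={"u1": 2.0, "u2": 0.3, "u3": 0.2, "u4": 0.1, "e": 0.25},
            family="poisson",
            seed=seed,
        )
        return simulate_dataset(4, 3, truth, grain="sorghum")
    if name == "zero-heavy":
        b = np.concatenate(
            [[1.6], [0.3, 0.2, -0.2, 0.1, -0.1], [-0.2, -0.15]]
        )
        truth = TruthRecord(
            b_true=b,
            sigma2_true={"u1": 1.0, "u2": 0.2, "u3": 0.2, "u4": 0.1, "e": 0.25},
            family="zip",
            pi_zero=0.4,
            seed=seed,
        )
        return simulate_dataset(6, 3, truth)
    raise SpecError(f"unknown scenario {name!r}; valid: {SCENARIOS}")
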