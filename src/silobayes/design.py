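"""Fixed-effect and random-effect incidence matrices for the factorial model.

The latent linear predictor is ``l = X b + Z1 u1 + Z2 u2 + Z3 u3 + Z4 u4 + e``
with b the systematic effects (intercept, fermentation period, inoculant),
u1 the taxon effects, u2 taxon x period, u3 taxon x inoculant and u4
taxon x period x inoculant.  Fixed effects use reference coding with CTRL and
period 0 (or the smallest observed levels) as references; each Z block is a
0/1 incidence matrix whose rows sum to 1.  Grain is not a model term: one
model is fitted per grain, matching the per-grain reporting of the study
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError
from .io import CountTable, INOCULANT_LEVELS, PERIOD_LEVELS

ALL_BLOCKS = ("u1", "u2", "u3", "u4")


@dataclass
class FactorialDesign:
    """Observation-level design: X plus the requested Z incidence blocks.

    ``z_index[k]`` holds, per observation, the column index into block k's
    effect vector (an equivalent, memory-light encoding of the 0/1 matrix
    Z_k, recoverable via :meth:`z_matrix`).  ``rows`` records the
    (taxon_id, sample_id) pair behind each observation, and ``y`` the count.
    """

    X: np.ndarray
    x_labels: list[str]
    z_index: dict[str, np.ndarray]
    z_labels: dict[str, list[tuple]]
    rows: list[tuple[str, str]]
    y: np.ndarray
    periods: list[int]
    inoculants: list[str]
    taxa: list[str]
    period_of_row: np.ndarray = field(default=None)
    inoculant_of_row: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(self.z_index)

    def z_matrix(self, block: str) -> np.ndarray:
        """Densify block ``block`` into its 0/1 incidence matrix."""
        idx = self.z_index[block]
        q = len(self.z_labels[block])
        Z = np.zeros((self.n, q))
        Z[np.arange(self.n), idx] = 1.0
        return Z

    def describe(self) -> dict:
        """Plain JSON-able description (dimensions and level labels) for audit."""
        return {
            "n": self.n,
            "x_columns": list(self.x_labels),
            "blocks": {
                k: {"columns": len(self.z_labels[k]), "labels": [list(map(str, t)) for t in self.z_labels[k]]}
                for k in self.z_index
            },
            "periods": list(self.periods),
            "inoculants": list(self.inoculants),
            "taxa": list(self.taxa),
        }


def build_design(
    table: CountTable,
    include_blocks: tuple[str, ...] | set[str] = ALL_BLOCKS,
    fill_zeros: bool = True,
) -> FactorialDesign:
    """Build X and the requested Z blocks from a count table.

    X has ``1 + (P-1) + (I-1)`` columns under reference coding with P observed
    periods and I observed inoculants; Z1 has one column per taxon, Z2 one per
    taxon x period, Z3 per taxon x inoculant, Z4 per taxon x period x
    inoculant.  Absent (taxon, sample) pairs become explicit zero counts
    unless ``fill_zeros`` is off.
    """
    include = tuple(b for b in ALL_BLOCKS if b in set(include_blocks))
    unknown = set(include_blocks) - set(ALL_BLOCKS)
    if unknown:
        raise DesignError(f"unknown random-effect block(s) {sorted(unknown)}; valid: {ALL_BLOCKS}")
    if not table.records:
        raise DesignError("empty count table")
    dense = table.densify(fill_zeros=fill_zeros)

    rows = sorted((t, s) for t, s, _ in dense.records)
    counts = {(t, s): c for t, s, c in dense.records}
    meta = dense.metadata

    periods = sorted({meta[s].period_days for _, s in rows},
                     key=lambda p: PERIOD_LEVELS.index(p))
    inoculants = sorted({meta[s].inoculant for _, s in rows},
                        key=lambda i: INOCULANT_LEVELS.index(i))
    taxa = sorted({t for t, _ in rows})

    n = len(rows)
    period_idx = np.array([periods.index(meta[s].period_days) for _, s in rows])
    inoc_idx = np.array([inoculants.index(meta[s].inoculant) for _, s in rows])
    taxon_idx = np.array([taxa.index(t) for t, _ in rows])

    # reference coding: intercept, then non-reference periods, then inoculants
    p_cols, i_cols = len(periods) - 1, len(inoculants) - 1
    X = np.zeros((n, 1 + p_cols + i_cols))
    X[:, 0] = 1.0
    x_labels = ["intercept"]
    for j, p in enumerate(periods[1:], start=1):
        X[:, j] = (period_idx == j).astype(float)
        x_labels.append(f"period[{p}]")
    for j, i in enumerate(inoculants[1:], start=1):
        X[:, p_cols + j] = (inoc_idx == j).astype(float)
        x_labels.append(f"inoculant[{i}]")
    if np.linalg.matrix_rank(X) < X.shape[1]:  # pragma: no cover - defensive
        raise DesignError("fixed-effect matrix is rank deficient")

    z_index: dict[str, np.ndarray] = {}
    z_labels: dict[str, list[tuple]] = {}
    for block in include:
        if block == "u1":
            labels = [(t,) for t in taxa]
            idx = taxon_idx
        elif block == "u2":
            if len(periods) < 2:
                raise DesignError("block u2 needs >= 2 period levels")
            labels = [(t, p) for t in taxa for p in periods]
            idx = taxon_idx * len(periods) + period_idx
        elif block == "u3":
            if len(inoculants) < 2:
                raise DesignError("block u3 needs >= 2 inoculant levels")
            labels = [(t, i) for t in taxa for i in inoculants]
            idx = taxon_idx * len(inoculants) + inoc_idx
        else:  # u4
            if len(periods) < 2 or len(inoculants) < 2:
                raise DesignError("block u4 needs >= 2 periods and >= 2 inoculants")
            labels = [(t, p, i) for t in taxa for p in periods for i in inoculants]
            idx = (taxon_idx * len(periods) + period_idx) * len(inoculants) + inoc_idx
        z_index[block] = idx.astype(np.intp)
        z_labels[block] = labels

    y = np.array([counts[r] for r in rows], dtype=float)
    return FactorialDesign(
        X=X,
        x_labels=x_labels,
        z_index=z_index,
        z_labels=z_labels,
        rows=rows,
        y=y,
        periods=periods,
        inoculants=inoculants,
        taxa=taxa,
        period_of_row=period_idx,
        inoculant_of_row=inoc_idx,
    )
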