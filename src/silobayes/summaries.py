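"""Posterior cell summaries and credibility-interval mean separation.

Each (inoculant, period) cell gets posterior draws of its linear predictor,
aggregated over taxa by averaging the included taxon-level random-effect
contributions (a balanced average, since the tables report one abundance
figure per cell despite taxon-level effects).  On the response scale the
exponential is applied draw-wise before summarizing, so the reported mean is
E[exp(l)], not exp(E[l]).

Mean separation follows the credibility-interval rule: two cells differ when
the equal-tailed interval of the difference of their draws excludes zero.
Letter codes come from an insert-and-absorb compact letter display: cells
sorted by descending mean share a letter iff they are not flagged different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecError, ValidationError
from .sampler import ChainResult

DIRECTIONS = ("inoculants-within-period", "periods-within-inoculant")


def cell_draws(
    result: ChainResult,
    scale: str = "response",
) -> dict[tuple[str, int], np.ndarray]:
    """Per-cell posterior draw vectors, keyed by (inoculant, period_days).

    ``scale`` is ``"latent"`` (log scale) or ``"response"`` (count scale,
    exp applied draw-wise).
    """
    if scale not in ("latent", "response"):
        raise SpecError(f"scale must be 'latent' or 'response', got {scale!r}")
    if len(result.periods) < 1 or len(result.inoculants) < 1:
        raise SpecError("chain lacks period/inoculant structure")
    b = result.draws["b"]
    n_taxa = max(len(result.taxa), 1)
    out: dict[tuple[str, int], np.ndarray] = {}
    for inoc in result.inoculants:
        for period in result.periods:
            l = b[:, 0].copy()
            lab_p, lab_i = f"period[{period}]", f"inoculant[{inoc}]"
            if lab_p in result.x_labels:
                l += b[:, result.x_labels.index(lab_p)]
            if lab_i in result.x_labels:
                l += b[:, result.x_labels.index(lab_i)]
            # balanced average of taxon-level contributions for this cell
            for block, labels in result.z_labels.items():
                u = result.draws[block]
                cols = [
                    j
                    for j, lab in enumerate(labels)
                    if (block == "u1")
                    or (block == "u2" and lab[1] == period)
                    or (block == "u3" and lab[1] == inoc)
                    or (block == "u4" and lab[1] == period and lab[2] == inoc)
                ]
                if len(cols) != n_taxa:  # pragma: no cover - defensive
                    raise SpecError(f"block {block}: expected {n_taxa} taxon columns, got {len(cols)}")
                l = l + u[:, cols].mean(axis=1)
            out[(inoc, period)] = np.exp(l) if scale == "response" else l
    return out


def comparison_sets(
    cells: dict[tuple[str, int], np.ndarray], direction: str
) -> dict[object, dict[object, np.ndarray]]:
    """Group cell draws into the comparison sets of the requested direction.

    ``inoculants-within-period`` compares the inoculant levels separately
    within each fermentation period (one set per period); the other
    direction swaps the roles.
    """
    if direction not in DIRECTIONS:
        raise SpecError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    sets: dict[object, dict[object, np.ndarray]] = {}
    for (inoc, period), draws in cells.items():
        if direction == "inoculants-within-period":
            sets.setdefault(period, {})[inoc] = draws
        else:
            sets.setdefault(inoc, {})[period] = draws
    return sets


def pairwise_separate(
    cells: dict[object, np.ndarray], level: float = 0.95
) -> pd.DataFrame:
    """Equal-tailed credibility intervals of all pairwise cell differences.

    Returns one row per unordered pair with the interval bounds and a
    ``different`` flag that is True iff the interval excludes zero.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    keys = list(cells)
    if len(keys) < 2:
        raise ValueError("need at least two cells to compare")
    alpha = 1.0 - level
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            diff = np.asarray(cells[a]) - np.asarray(cells[b])
            lo, hi = np.quantile(diff, [alpha / 2.0, 1.0 - alpha / 2.0])
            rows.append((a, b, float(lo), float(hi), bool(lo > 0.0 or hi < 0.0)))
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "lower", "upper", "different"])


def letter_display(
    means: dict[object, float], flags: dict[frozenset, bool]
) -> dict[object, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Cells are sorted by descending mean; each significant pair splits every
    letter column containing both, and columns that become subsets of others
    are absorbed.  Two cells never share a letter when flagged different, and
    always share at least one when not.
    """
    keys = sorted(means, key=lambda k: -means[k])
    for pair in flags:
        if len(pair) != 2 or not pair <= set(keys):
            raise ValidationError(f"flag key {set(pair)} is not a pair of known cells")
    different = {pair for pair, d in flags.items() if d}

    columns: list[set] = [set(keys)]
    for pair in sorted(different, key=lambda p: sorted(str(k) for k in p)):
        a, b = sorted(pair, key=lambda k: keys.index(k))
        new_columns: list[set] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {b})
                new_columns.append(col - {a})
            else:
                new_columns.append(col)
        # absorb subsets
        columns = []
        for col in sorted(new_columns, key=len, reverse=True):
            if not any(col <= other for other in columns):
                columns.append(col)
    columns.sort(key=lambda col: min(keys.index(k) for k in col))
    letters = {k: "" for k in keys}
    for j, col in enumerate(columns):
        letter = chr(ord("a") + j) if j < 26 else f"a{j}"
        for k in col:
            letters[k] += letter
    if any(not v for v in letters.values()):  # pragma: no cover - defensive
        raise ValidationError("letter display left a cell unlettered")
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def posterior_cv(draws: np.ndarray) -> float:
    """Coefficient of variation of posterior draws: sd (n-1 denominator) / mean."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    mean = float(draws.mean())
    if mean == 0.0:
        raise ZeroDivisionError("posterior mean is zero; CV undefined")
    if draws.size == 1:
        return 0.0
    return float(draws.std(ddof=1) / mean)


@dataclass
class CellSummaryTable:
    """Tidy per-cell posterior summary with separation letters."""

    frame: pd.DataFrame
    direction: str
    level: float

    def pivot(self) -> pd.DataFrame:
        """Wide layout: rows = inoculant, columns = Mean/CV per period."""
        f = self.frame.copy()
        f["display"] = [f"{m:.4g}^{lt}" for m, lt in zip(f["mean"], f["letters"])]
        wide = f.pivot(index="inoculant", columns="period_days", values=["display", "cv"])
        return wide


def summary_table(
    result: ChainResult,
    direction: str = "inoculants-within-period",
    level: float = 0.95,
    scale: str = "response",
) -> CellSummaryTable:
    """Posterior mean, CV, credibility bounds and letters per cell.

    Separation letters are computed within each comparison set of
    ``direction`` (e.g. among inoculants, separately for every period).
    """
    cells = cell_draws(result, scale=scale)
    sets = comparison_sets(cells, direction)
    alpha = 1.0 - level
    rows = []
    for group_key, group in sets.items():
        sep = pairwise_separate(group, level=level)
        flags = {
            frozenset((r.cell_a, r.cell_b)): bool(r.different)
            for r in sep.itertuples(index=False)
        }
        means = {k: float(np.mean(v)) for k, v in group.items()}
        letters = letter_display(means, flags)
        for k, draws in group.items():
            lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
            inoc, period = (
                (k, group_key) if direction == "inoculants-within-period" else (group_key, k)
            )
            rows.append(
                dict(
                    inoculant=inoc,
                    period_days=period,
                    mean=means[k],
                    cv=posterior_cv(draws),
                    lower=float(lo),
                    upper=float(hi),
                    letters=letters[k],
                )
            )
    frame = pd.DataFrame(rows).sort_values(["period_days", "inoculant"], ignore_index=True)
    return CellSummaryTable(frame=frame, direction=direction, level=level)
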