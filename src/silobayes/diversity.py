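"""Alpha-diversity statistics and sequencing-depth standardization.

Implements the community summaries reported alongside the abundance models:
Chao1 richness, Pielou's evenness J, the Gini-Simpson index (with the
inverse-Simpson form behind a flag), rarefaction of samples to a common read
depth by subsampling without replacement, and rarefaction curves via the
closed-form hypergeometric expectation of observed richness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountTable


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0) or np.any(c != np.floor(c)):
        raise ValidationError("counts must be non-negative integers")
    if c.sum() == 0:
        raise ValidationError("empty sample: all counts are zero")
    return c


def chao1(counts) -> float:
    """Chao1 richness estimate.

    S_obs + F1^2 / (2 F2) when doubletons exist; the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0 (avoids division by zero).
    F1 and F2 are the numbers of taxa seen exactly once and twice.
    """
    c = _as_counts(counts)
    s_obs = float(np.sum(c > 0))
    f1 = float(np.sum(c == 1))
    f2 = float(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def gini_simpson(counts, inverse: bool = False) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (or inverse Simpson 1/sum p_i^2)."""
    c = _as_counts(counts)
    p = c / c.sum()
    d = float(np.sum(p * p))
    return 1.0 / d if inverse else 1.0 - d


def pielou_evenness(counts) -> float:
    """Pielou's J: Shannon entropy (natural log) over ln(observed richness).

    Undefined for single-taxon samples (ln 1 = 0).
    """
    c = _as_counts(counts)
    c = c[c > 0]
    if c.size < 2:
        raise ValidationError("evenness undefined for a single-taxon sample")
    p = c / c.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / float(np.log(c.size))


def subsample_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` reads without replacement from an abundance vector."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return c.copy()
    # sequential (multivariate) hypergeometric draw
    out = np.zeros_like(c)
    remaining_total = total
    remaining_draw = depth
    for i, ci in enumerate(c):
        if remaining_draw == 0:
            break
        take = rng.hypergeometric(int(ci), remaining_total - int(ci), remaining_draw)
        out[i] = take
        remaining_draw -= int(take)
        remaining_total -= int(ci)
    return out


def rarefy(table: CountTable, depth: int, seed: int = 0, drop_shallow: bool = False) -> CountTable:
    """Standardize every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` raise unless ``drop_shallow`` is
    set, in which case they are removed with a warning.  Deterministic per
    seed (one derived stream per sample, keyed by sorted sample order).
    """
    if depth < 1:
        raise ValueError("depth must be a positive read count")
    dense = table.densify()
    taxa, samples = dense.taxa, dense.samples
    mat = {s: np.zeros(len(taxa), dtype=np.int64) for s in samples}
    for t, s, c in dense.records:
        mat[s][taxa.index(t)] = c
    root = np.random.SeedSequence(seed)
    streams = dict(zip(samples, root.spawn(len(samples))))
    records: list[tuple[str, str, int]] = []
    kept_meta = {}
    for s in samples:
        total = int(mat[s].sum())
        if total < depth:
            if not drop_shallow:
                raise ValidationError(
                    f"sample {s!r} has {total} reads < depth {depth}; "
                    "set drop_shallow to discard it"
                )
            warnings.warn(f"dropping sample {s!r} ({total} reads < depth {depth})", stacklevel=2)
            continue
        sub = subsample_counts(mat[s], depth, np.random.default_rng(streams[s]))
        records.extend((taxa[j], s, int(sub[j])) for j in range(len(taxa)))
        kept_meta[s] = table.metadata[s]
    return CountTable(records=records, metadata=kept_meta)


def expected_richness(counts, depth: int) -> float:
    """Closed-form expected observed richness after rarefying to ``depth``.

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)), the hypergeometric
    probability that taxon i appears at least once among d of the N reads.
    Computed via log-gamma for numerical range.
    """
    from scipy.special import gammaln as gl

    c = _as_counts(counts)
    c = c[c > 0]
    total = c.sum()
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds sample total {int(total)}")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    def log_comb(n, k):
        return gl(n + 1.0) - gl(k + 1.0) - gl(n - k + 1.0)

    miss = np.where(
        total - c >= depth,
        np.exp(log_comb(total - c, depth) - log_comb(total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - miss))


def rarefaction_curve(
    counts,
    depths,
    replicates: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected observed richness over a grid of depths.

    The default (``replicates=0``) uses the exact hypergeometric expectation,
    which is non-decreasing and concave in depth; ``replicates > 0`` switches
    to the Monte-Carlo mean over that many subsamples.
    """
    c = _as_counts(counts).astype(np.int64)
    depths = [int(d) for d in depths]
    rows = []
    rng = np.random.default_rng(seed)
    for d in depths:
        if replicates > 0:
            rich = float(
                np.mean(
                    [np.sum(subsample_counts(c, d, rng) > 0) for _ in range(replicates)]
                )
            )
        else:
            rich = expected_richness(c, d)
        rows.append((d, rich))
    return pd.DataFrame(rows, columns=["depth", "richness"])


def alpha_diversity_table(
    table: CountTable,
    rarefy_depth: int | None = None,
    seed: int = 0,
    inverse_simpson: bool = False,
    drop_shallow: bool = False,
) -> pd.DataFrame:
    """Per-sample Chao1, Pielou evenness and (Gini-)Simpson diversity.

    With ``rarefy_depth`` the table is first standardized to that depth, the
    depth-standardization step applied before the study's diversity panels.
    Samples where an index is undefined (single observed taxon) get NaN for
    that index.
    """
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed=seed, drop_shallow=drop_shallow)
    dense = table.densify()
    taxa = dense.taxa
    rows = []
    by_sample: dict[str, np.ndarray] = {s: np.zeros(len(taxa)) for s in dense.samples}
    for t, s, c in dense.records:
        by_sample[s][taxa.index(t)] = c
    for s in dense.samples:
        c = by_sample[s]
        if c.sum() == 0:
            continue
        try:
            j = pielou_evenness(c)
        except ValidationError:
            j = float("nan")
        rows.append(
            dict(
                sample_id=s,
                chao1=chao1(c),
                evenness=j,
                simpson=gini_simpson(c, inverse=inverse_simpson),
                depth_used=int(c.sum()),
            )
        )
    return pd.DataFrame(rows)
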