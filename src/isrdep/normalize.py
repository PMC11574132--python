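"""RNA-seq preprocessing chain.

Order of operations (the microarray path skips this module entirely and
enters downstream already on log2 scale):

1. gene-length normalization of raw counts (reads per kilobase),
2. counts-per-million depth normalization,
3. pedestal (+2) then log2,
4. cyclic-loess cross-sample normalization (pairwise MA trends),
5. lowess noise-floor/ceiling modeling on per-group rank-expression
   trends, with flooring/ceiling and removal of noise-biased genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, group_samples, validate_design, GROUPS

DEFAULT_PEDESTAL = 2.0
DEFAULT_SPAN = 0.3
DEFAULT_TOLERANCE = 0.5
DEFAULT_BAND = (0.25, 0.75)


class NormalizationError(ValueError):
    pass


def length_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide counts by gene length in kilobases (reads per kilobase)."""
    if m.scale != "counts":
        raise NormalizationError(f"length_normalize expects counts, got {m.scale}")
    if m.lengths_bp is None:
        raise NormalizationError("gene lengths required for length normalization")
    values = m.values.div(m.lengths_bp / 1000.0, axis=0)
    return ExpressionMatrix(values=values, scale="counts", lengths_bp=m.lengths_bp)


def cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: scale each sample column to sum to 1e6."""
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise NormalizationError(f"degenerate samples with zero column sum: {list(zero.index)}")
    values = m.values.mul(1e6 / colsums, axis=1)
    return m.copy_with(values)


def pedestal_log2(m: ExpressionMatrix, c: float = DEFAULT_PEDESTAL) -> ExpressionMatrix:
    """log2(x + c); the pedestal stabilizes values near zero."""
    if not c > 0:
        raise NormalizationError("pedestal constant must be > 0")
    if (m.values.to_numpy() < 0).any():
        raise NormalizationError("pedestal_log2 requires non-negative values")
    return m.copy_with(np.log2(m.values + c), scale="log2")


def cyclic_loess(
    m: ExpressionMatrix, span: float = DEFAULT_SPAN, iterations: int = 1
) -> ExpressionMatrix:
    """Pairwise MA-trend normalization cycled over all sample pairs.

    For each pair (i, j): fit a lowess trend of M = x_i - x_j on
    A = (x_i + x_j)/2 and move each sample half the fitted trend toward
    the other. One iteration visits every unordered pair once. The grand
    mean is preserved exactly (each pairwise adjustment is antisymmetric).
    """
    if not (0 < span <= 1):
        raise NormalizationError("span must be in (0, 1]")
    if m.values.shape[1] < 2:
        raise NormalizationError("cyclic loess needs at least 2 samples")
    x = m.values.to_numpy(dtype=float).copy()
    n_samples = x.shape[1]
    for _ in range(iterations):
        # all pairwise trends are fitted against the cycle's starting
        # matrix and applied together, so the result is equivariant under
        # sample permutation
        adjust = np.zeros_like(x)
        for i, j in itertools.combinations(range(n_samples), 2):
            a = 0.5 * (x[:, i] + x[:, j])
            mm = x[:, i] - x[:, j]
            delta = 0.01 * (a.max() - a.min())
            fit = lowess(mm, a, frac=span, delta=delta, return_sorted=False)
            adjust[:, i] -= fit / 2.0
            adjust[:, j] += fit / 2.0
        # average over the n-1 pairs each sample participates in, so one
        # cycle is a single balanced correction per sample
        x += adjust / max(n_samples - 1, 1)
    values = pd.DataFrame(x, index=m.values.index, columns=m.values.columns)
    return m.copy_with(values, scale="normalized_log2")


@dataclass
class NoiseModel:
    """Per-group rank-expression lowess trends and derived cutoffs.

    The floor (and optional ceiling) cutoff marks where a group's
    rank-ordered mean-expression trend departs from the straight line
    fitted through its central rank band — the edge of the platform's
    linear dynamic range. ``trends`` maps group -> DataFrame(rank,
    gene_id, mean, fitted).
    """

    floor_cutoff: float
    ceiling_cutoff: float | None
    trends: dict[str, pd.DataFrame]
    span: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.ceiling_cutoff is not None and self.floor_cutoff > self.ceiling_cutoff:
            raise NormalizationError("floor_cutoff exceeds ceiling_cutoff")


def _group_trend(means: pd.Series, span: float) -> pd.DataFrame:
    order = np.argsort(means.to_numpy(), kind="stable")
    sorted_means = means.to_numpy()[order]
    ranks = np.arange(1, len(sorted_means) + 1, dtype=float)
    fitted = lowess(sorted_means, ranks, frac=span, delta=0.01 * len(ranks), return_sorted=False)
    # enforce the monotone non-decreasing trend invariant (lowess on sorted
    # data can wiggle slightly at the ends)
    fitted = np.maximum.accumulate(fitted)
    return pd.DataFrame(
        {"rank": ranks, "gene_id": means.index.to_numpy()[order], "mean": sorted_means,
         "fitted": fitted}
    )


def fit_noise_model(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    tolerance: float = DEFAULT_TOLERANCE,
    band: tuple[float, float] = DEFAULT_BAND,
) -> NoiseModel:
    """Model the noise floor/ceiling from per-group rank-expression trends.

    Per group: rank genes by group-mean expression, fit a lowess trend of
    mean vs. rank, fit a straight line to the central rank band (default
    25th-75th percentile), and set the floor where the trend deviates from
    that line by more than ``tolerance`` below the band (ceiling
    symmetrically above). Cutoffs combine conservatively across groups:
    highest floor, lowest ceiling.
    """
    validate_design(design)
    if m.values.shape[0] < 10:
        raise NormalizationError("need at least 10 genes to fit a noise model")
    floors, ceilings, trends = [], [], {}
    for group in GROUPS:
        cols = group_samples(design, group)
        means = m.values[cols].mean(axis=1)
        trend = _group_trend(means, span)
        trends[group] = trend
        ranks = trend["rank"].to_numpy()
        fitted = trend["fitted"].to_numpy()
        n = len(ranks)
        lo_idx = int(np.floor(band[0] * (n - 1)))
        hi_idx = int(np.ceil(band[1] * (n - 1)))
        slope, intercept = np.polyfit(ranks[lo_idx: hi_idx + 1], fitted[lo_idx: hi_idx + 1], 1)
        line = intercept + slope * ranks
        dev = np.abs(fitted - line)

        # a deviating region below the band marks the noise plateau plus its
        # transition into the linear range; the cutoff is placed at the end
        # of the plateau — the highest deviating rank whose trend value is
        # still within tolerance of the plateau level — so it tracks the
        # floor itself rather than the smoothing-dependent transition
        below = np.nonzero((np.arange(n) < lo_idx) & (dev > tolerance))[0]
        if len(below):
            plateau = fitted[below.min()]
            near_plateau = below[fitted[below] <= plateau + tolerance]
            floors.append(float(fitted[near_plateau.max()]))
        else:
            floors.append(float(trend["mean"].iloc[0]))
        above = np.nonzero((np.arange(n) > hi_idx) & (dev > tolerance))[0]
        if len(above):
            shoulder = fitted[above.max()]
            near_shoulder = above[fitted[above] >= shoulder - tolerance]
            ceilings.append(float(fitted[near_shoulder.min()]))
        else:
            ceilings.append(None)

    floor = max(floors)
    finite_ceils = [c for c in ceilings if c is not None]
    ceiling = min(finite_ceils) if finite_ceils else None
    if ceiling is not None and ceiling < floor:
        # degenerate separation: fall back to an inert ceiling
        ceiling = None
    return NoiseModel(
        floor_cutoff=floor, ceiling_cutoff=ceiling, trends=trends, span=span, tolerance=tolerance
    )


def apply_noise_model(
    m: ExpressionMatrix, nm: NoiseModel
) -> tuple[ExpressionMatrix, list[str]]:
    """Floor/ceil values at the cutoffs and drop noise-biased genes.

    A gene with no sample above the floor (or, when a ceiling is set, no
    sample below the ceiling) carries no usable dynamic range and is
    removed; its id is returned in the removal list.
    """
    values = m.values.copy()
    removed_floor = (values <= nm.floor_cutoff).all(axis=1)
    removed = values.index[removed_floor].tolist()
    if nm.ceiling_cutoff is not None:
        removed_ceiling = (values >= nm.ceiling_cutoff).all(axis=1)
        removed += values.index[removed_ceiling & ~removed_floor].tolist()
        values = values.clip(upper=nm.ceiling_cutoff)
    values = values.clip(lower=nm.floor_cutoff)
    kept = values.drop(index=removed)
    return m.copy_with(kept), removed


def rnaseq_preprocess(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    pedestal: float = DEFAULT_PEDESTAL,
    span: float = DEFAULT_SPAN,
    tolerance: float = DEFAULT_TOLERANCE,
    iterations: int = 1,
) -> tuple[ExpressionMatrix, NoiseModel, list[str]]:
    """Full chain: length-normalize, CPM, pedestal+log2, cyclic loess, noise filter."""
    out = length_normalize(m)
    out = cpm(out)
    out = pedestal_log2(out, pedestal)
    out = cyclic_loess(out, span=span, iterations=iterations)
    nm = fit_noise_model(out, design, span=span, tolerance=tolerance)
    filtered, removed = apply_noise_model(out, nm)
    return filtered, nm, removed
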