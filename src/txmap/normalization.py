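"""Sample-level normalization chain.

The chain that puts heterogeneous platforms on one comparable scale is

1. :func:`linearize` — undo any log transform declared for the deposit;
2. :func:`replace_nonpositive` — substitute values <= 0 with 95% of the
   sample's minimum positive value, so ratios stay defined and a
   below-detection signal still registers as "low";
3. :func:`normalize_intra` — rescale each sample to percent of its mean
   (intra-sample normalization), removing per-sample intensity scale;
4. :func:`scaled_quantile_normalize` — map every sample onto a shared
   reference quantile curve (inter-sample normalization) that accommodates
   platforms of different sizes.

Steps 1–3 act on one sample's values; step 4 acts jointly on all samples of
the two pools being compared, so pooled ratios live on one common scale.

The scaled quantile normalization is defined as follows.  Each sample's
empirical quantile function (linear interpolation between order statistics,
midrank positions for ties) is evaluated on a common probability grid; the
reference curve is the pointwise mean of these per-sample curves; each value
is then replaced by the reference curve evaluated at the value's own
within-sample quantile.  The grid is the union of ``quantile_grid_size``
equally spaced probabilities and every sample's own quantile knots, which
makes the piecewise-linear mean curve exact: two identical samples map to
themselves, and equal-length samples end up with identical sorted vectors
(the classical quantile-normalization property).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "NormalizationParams",
    "linearize",
    "replace_nonpositive",
    "normalize_intra",
    "scaled_quantile_normalize",
]

_LINEARIZERS = {
    "linear": lambda x: x,
    "log2": lambda x: np.power(2.0, x),
    "log10": lambda x: np.power(10.0, x),
    "ln": np.exp,
}


@dataclass
class NormalizationParams:
    """Tunables of the normalization chain.

    nonpositive_factor
        Fraction of the sample's minimum positive value substituted for
        values <= 0 (default 0.95, i.e. 95%).
    quantile_grid_size
        Number of equally spaced probabilities seeding the reference-curve
        grid for inter-sample normalization.
    """

    nonpositive_factor: float = 0.95
    quantile_grid_size: int = 1001

    def __post_init__(self) -> None:
        if not (0.0 < self.nonpositive_factor < 1.0):
            raise ValidationError(
                f"nonpositive_factor must be in (0, 1), got {self.nonpositive_factor}"
            )
        if self.quantile_grid_size < 2:
            raise ValidationError(
                f"quantile_grid_size must be >= 2, got {self.quantile_grid_size}"
            )


def linearize(values, scale: str) -> np.ndarray:
    """Convert deposited values to the linear intensity scale.

    ``scale`` is one of ``linear`` (identity), ``log2``, ``log10``, ``ln``.
    NaN (missing) propagates unchanged.
    """
    try:
        fn = _LINEARIZERS[scale]
    except KeyError:
        raise ValidationError(
            f"unknown scale tag {scale!r}; expected one of {sorted(_LINEARIZERS)}"
        ) from None
    return fn(np.asarray(values, dtype=float))


def replace_nonpositive(values, factor: float = 0.95) -> np.ndarray:
    """Replace values <= 0 by ``factor`` x the sample's minimum positive value.

    Positive values are untouched; NaN propagates.  Raises if the sample has
    no positive signal at all.
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    positive = finite & (x > 0)
    if not positive.any():
        raise ValidationError("sample has no positive signal")
    floor = factor * x[positive].min()
    x[finite & (x <= 0)] = floor
    return x


def normalize_intra(values) -> np.ndarray:
    """Rescale a sample to percent of its mean (output mean = 100)."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if x.size == 0 or not finite.any():
        raise ValidationError("normalize_intra: empty sample")
    return 100.0 * x / x[finite].mean()


def _midrank_probs(x: np.ndarray) -> np.ndarray:
    """Within-sample empirical quantile of each value, midrank convention.

    Uses plotting positions (r - 1)/(m - 1) so that a value sitting exactly
    on an order statistic maps back to itself through its own quantile curve.
    """
    m = x.size
    if m == 1:
        return np.array([0.5])
    ranks = rankdata(x, method="average")
    return (ranks - 1.0) / (m - 1.0)


def scaled_quantile_normalize(
    samples, params: NormalizationParams | None = None
) -> list[np.ndarray]:
    """Inter-sample normalization onto the mean quantile curve.

    ``samples`` is a sequence of 1-D value arrays, possibly of different
    lengths (different platforms).  Within-sample rank order is preserved;
    output lengths equal input lengths; NaNs stay NaN in place.
    """
    if params is None:
        params = NormalizationParams()
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValidationError("scaled quantile normalization needs >= 2 samples")
    finites = [np.isfinite(a) for a in arrays]
    for i, (a, f) in enumerate(zip(arrays, finites)):
        if a.size == 0 or not f.any():
            raise ValidationError(f"sample #{i} is empty")

    # probability grid: equally spaced seeds plus every sample's own knots,
    # so interpolating the piecewise-linear mean curve is exact
    pieces = [np.linspace(0.0, 1.0, params.quantile_grid_size)]
    for a, f in zip(arrays, finites):
        m = int(f.sum())
        if m >= 2:
            pieces.append(np.linspace(0.0, 1.0, m))
    grid = np.unique(np.concatenate(pieces))

    reference = np.zeros_like(grid)
    for a, f in zip(arrays, finites):
        reference += np.quantile(a[f], grid)
    reference /= len(arrays)

    out: list[np.ndarray] = []
    for a, f in zip(arrays, finites):
        res = np.full(a.shape, np.nan)
        probs = _midrank_probs(a[f])
        res[f] = np.interp(probs, grid, reference)
        out.append(res)
    return out
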