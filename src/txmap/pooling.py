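"""Integration of normalized data points into per-condition pooled tables.

A *pool* is one biological condition; its expression table assigns every
locus the mean of all its data points (probe-spot measurements across all
samples of the pool, flattened and unweighted), together with the number of
data points and the standard deviation expressed as percent of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ValidationError
from .io import LocusDataPoints

__all__ = ["PoolExpression", "pool_values", "pool_frame", "compute_pool_correlation"]

POOL_COLUMNS = ["mean_value", "n_points", "sd_percent"]


@dataclass
class PoolExpression:
    """Per-locus integrated summary for one condition.

    ``table`` is indexed by locus symbol with columns ``mean_value``
    (normalized units), ``n_points`` (data-point count) and ``sd_percent``
    (population SD as percent of the mean; 0 when n_points == 1).
    """

    pool_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in POOL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"pool table missing columns {missing}")
        t = self.table
        if (t["n_points"] < 1).any():
            raise ValidationError("pool table lists a locus with zero data points")
        if (t["mean_value"] <= 0).any():
            raise ValidationError("pool table contains a non-positive mean value")

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def total_data_points(self) -> int:
        return int(self.table["n_points"].sum())


def pool_frame(points: pd.DataFrame, pool_id: str) -> PoolExpression:
    """Pool a long data-point frame with columns ``symbol`` and ``value``."""
    if points.empty:
        return PoolExpression(pool_id, pd.DataFrame(columns=POOL_COLUMNS))
    g = points.groupby("symbol")["value"]
    mean = g.mean()
    n = g.size()
    sd = g.std(ddof=0).fillna(0.0)  # population SD; single point -> 0
    table = pd.DataFrame(
        {"mean_value": mean, "n_points": n, "sd_percent": 100.0 * sd / mean}
    ).sort_index()
    return PoolExpression(pool_id, table)


def pool_values(
    points_by_locus: Iterable[LocusDataPoints] | Sequence[LocusDataPoints],
    pool_id: str = "pool",
) -> PoolExpression:
    """Integrate all data points of one condition into a pooled table.

    Points are flattened across samples (a 3-probe sample contributes 3
    points where a 1-probe sample contributes 1).  Loci with zero points are
    simply absent from the result.
    """
    symbols: list[str] = []
    values: list[float] = []
    for ldp in points_by_locus:
        for _, v in ldp.points:
            symbols.append(ldp.symbol)
            values.append(float(v))
    return pool_frame(pd.DataFrame({"symbol": symbols, "value": values}), pool_id)


def compute_pool_correlation(
    pool_x: PoolExpression, pool_y: PoolExpression
) -> tuple[float, float]:
    """Pearson correlation of log10 pooled means over shared loci.

    Returns ``(r, p)`` with the two-sided p-value from the standard
    t transform.  Requires at least 3 shared loci.
    """
    shared = pool_x.table.index.intersection(pool_y.table.index)
    if len(shared) < 3:
        raise ValidationError(
            f"pool correlation needs >= 3 shared loci, got {len(shared)}"
        )
    x = np.log10(pool_x.table.loc[shared, "mean_value"].to_numpy())
    y = np.log10(pool_y.table.loc[shared, "mean_value"].to_numpy())
    r, p = pearsonr(x, y)
    return float(r), float(p)
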