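"""Differential transcriptome mapping between two pooled conditions.

Given two pooled per-locus tables this module computes, in order:

* per-locus expression ratios A/B for loci measured in both pools;
* extreme-gene flags — loci whose ratio falls in the highest or lowest
  tail (default 2.5th percentile) of the ratio distribution;
* a sliding-window segment map — fixed windows (default 500 kb, shifted by
  250 kb) scored for enrichment of extreme genes by the hypergeometric
  upper-tail test, corrected for multiple comparison, called when q < 0.05
  with at least 3 extreme genes, and deduplicated when overlapping calls
  share most of their flagged genes;
* a single-gene map — the same machinery at a 12.5-kb window (about a
  quarter of a mean gene length) with a 1-gene minimum, plus the "prevail"
  rule when a window holds more than one locus;
* per-chromosome median ratios (dosage trends, e.g. ~1.5 on a trisomic
  chromosome);
* ranked most over-/under-expressed gene lists among loci with enough
  data points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import LocusAnnotation

__all__ = [
    "MapParams",
    "compute_differential",
    "annotate_entries",
    "flag_extremes",
    "build_windows",
    "segment_pvalue",
    "correct_q",
    "call_segments",
    "single_gene_map",
    "chromosome_medians",
    "top_genes",
]

_CORRECTIONS = {"bh": "fdr_bh", "bonferroni": "bonferroni"}


@dataclass
class MapParams:
    """Windowing and calling parameters of the differential map.

    window, shift
        Segment window size and shift in bp (defaults 500,000 / 250,000).
    gene_window
        Window size for the single-gene map in bp (default 12,500; the
        shift is half the window).
    tail
        Fraction of the ratio distribution flagged at each extreme
        (default 0.025, i.e. the 2.5th percentiles).
    q_threshold
        Corrected significance threshold for a call (default 0.05).
    min_extreme_genes
        Minimum flagged genes a called segment must contain (default 3).
    min_data_points
        Minimum data points per pool for the ranked gene lists (default 5).
    correction
        Multiple-comparison correction: ``bh`` or ``bonferroni``.
    """

    window: int = 500_000
    shift: int = 250_000
    gene_window: int = 12_500
    tail: float = 0.025
    q_threshold: float = 0.05
    min_extreme_genes: int = 3
    min_data_points: int = 5
    correction: str = "bh"

    def __post_init__(self) -> None:
        if not (self.window >= self.shift > 0):
            raise ValidationError(
                f"require window >= shift > 0, got {self.window}/{self.shift}"
            )
        if not (0.0 <= self.tail < 0.5):
            raise ValidationError(f"tail must be in [0, 0.5), got {self.tail}")
        if self.gene_window < 2:
            raise ValidationError("gene_window must be >= 2 bp")
        if self.correction not in _CORRECTIONS:
            raise ValidationError(
                f"correction must be one of {sorted(_CORRECTIONS)}"
            )


ENTRY_COLUMNS = [
    "symbol", "value_A", "value_B", "ratio",
    "n_points_A", "n_points_B", "sd_percent_A", "sd_percent_B", "flag",
]


def compute_differential(pool_a, pool_b) -> pd.DataFrame:
    """Per-locus A/B ratio table over loci measured in both pools.

    Returns one row per shared locus with the pooled means, their ratio,
    data-point counts and SD%, and a ``flag`` column initialized to
    ``none`` (set later by :func:`flag_extremes`).
    """
    shared = pool_a.table.index.intersection(pool_b.table.index).sort_values()
    if len(shared) == 0:
        raise ValidationError("no loci shared between the two pools")
    a = pool_a.table.loc[shared]
    b = pool_b.table.loc[shared]
    entries = pd.DataFrame({
        "symbol": shared,
        "value_A": a["mean_value"].to_numpy(),
        "value_B": b["mean_value"].to_numpy(),
        "ratio": a["mean_value"].to_numpy() / b["mean_value"].to_numpy(),
        "n_points_A": a["n_points"].to_numpy(),
        "n_points_B": b["n_points"].to_numpy(),
        "sd_percent_A": a["sd_percent"].to_numpy(),
        "sd_percent_B": b["sd_percent"].to_numpy(),
        "flag": "none",
    })
    return entries


def annotate_entries(
    entries: pd.DataFrame, annotation: Sequence[LocusAnnotation]
) -> pd.DataFrame:
    """Attach chromosome/start/end/cytoband columns from the annotation."""
    ann = pd.DataFrame(
        [(a.symbol, a.chromosome, a.start, a.end, a.cytoband) for a in annotation],
        columns=["symbol", "chromosome", "start", "end", "cytoband"],
    )
    merged = entries.merge(ann, on="symbol", how="left")
    missing = merged["chromosome"].isna()
    if missing.any():
        bad = merged.loc[missing, "symbol"].iloc[0]
        raise ValidationError(f"locus {bad!r} has entries but no annotation")
    return merged


def flag_extremes(entries: pd.DataFrame, tail: float = 0.025) -> pd.DataFrame:
    """Flag loci in the extreme tails of the ratio distribution.

    Thresholds are the empirical ``tail`` and ``1 - tail`` quantiles of the
    ratio distribution over all entries; comparisons are inclusive, so ties
    sitting exactly on a threshold are flagged.  ``tail == 0`` flags nothing.
    The thresholds are recorded in ``result.attrs["ratio_thresholds"]``.
    """
    if entries.empty:
        raise ValidationError("flag_extremes: no entries")
    out = entries.copy()
    out["flag"] = "none"
    if tail <= 0.0:
        out.attrs["ratio_thresholds"] = (math.nan, math.nan)
        return out
    ratios = out["ratio"].to_numpy()
    lower = float(np.quantile(ratios, tail))
    upper = float(np.quantile(ratios, 1.0 - tail))
    out.loc[out["ratio"] >= upper, "flag"] = "over"
    out.loc[out["ratio"] <= lower, "flag"] = "under"
    out.attrs["ratio_thresholds"] = (lower, upper)
    return out


def build_windows(
    annotation: Sequence[LocusAnnotation], window: int = 500_000,
    shift: int = 250_000,
) -> pd.DataFrame:
    """Full sliding-window grid covering every annotated chromosome.

    Per chromosome the grid is [1 + i*shift, window + i*shift] for
    i = 0, 1, ... while the window start does not exceed the chromosome
    extent (the maximum annotated end coordinate).
    """
    if not annotation:
        raise ValidationError("build_windows: empty annotation")
    extents: dict[str, int] = {}
    for a in annotation:
        extents[a.chromosome] = max(extents.get(a.chromosome, 0), a.end)
    chroms, starts = [], []
    for chrom in extents:  # preserves annotation order of first appearance
        extent = extents[chrom]
        n = extent // shift + (1 if extent % shift else 0)
        s = 1 + shift * np.arange(n, dtype=np.int64)
        s = s[s <= extent]
        chroms.extend([chrom] * len(s))
        starts.append(s)
    start = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    return pd.DataFrame(
        {"chromosome": chroms, "start": start, "end": start + window - 1}
    )


def segment_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Hypergeometric enrichment p-value P[X >= k].

    ``N`` loci carry ratios genome-wide, ``K`` of them are flagged in the
    tail under test, the segment holds ``n`` loci of which ``k`` are flagged.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent parameters N={N} K={K} n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(
            f"inconsistent count k={k}, valid range is [0, {min(K, n)}]"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def correct_q(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-comparison correction over a family of segment tests.

    ``bh`` gives Benjamini–Hochberg step-up q-values; ``bonferroni`` the
    Bonferroni-adjusted p-values (clipped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method=_CORRECTIONS[method])[1]


def _window_index_span(start: np.ndarray, window: int, shift: int):
    """Range of window indices whose [1+i*shift, window+i*shift] holds start."""
    i_hi = (start - 1) // shift
    i_lo = np.maximum(0, -((start - window) // -shift))  # ceil division
    return i_lo, i_hi


def _aggregate_windows(
    entries: pd.DataFrame, window: int, shift: int
) -> pd.DataFrame:
    """Per-occupied-window aggregates of the entry table.

    A locus belongs to every window containing its start coordinate.
    Returns one row per (chromosome, window start) actually holding loci,
    with counts, flagged counts, member/flagged symbol lists and the
    per-pool member means.
    """
    for col in ("chromosome", "start", "ratio", "flag", "value_A", "value_B"):
        if col not in entries.columns:
            raise ValidationError(f"entries lack required column {col!r}")
    start = entries["start"].to_numpy(dtype=np.int64)
    i_lo, i_hi = _window_index_span(start, window, shift)
    counts = (i_hi - i_lo + 1).astype(np.int64)
    row_idx = np.repeat(np.arange(len(entries)), counts)
    # window index for each (entry, window) membership pair
    offsets = np.concatenate([np.arange(c) for c in counts]) if len(counts) else \
        np.array([], dtype=np.int64)
    win_i = np.repeat(i_lo, counts) + offsets

    long = pd.DataFrame({
        "chromosome": entries["chromosome"].to_numpy()[row_idx],
        "win_start": 1 + win_i * shift,
        "symbol": entries["symbol"].to_numpy()[row_idx],
        "ratio": entries["ratio"].to_numpy()[row_idx],
        "flag": entries["flag"].to_numpy()[row_idx],
        "value_A": entries["value_A"].to_numpy()[row_idx],
        "value_B": entries["value_B"].to_numpy()[row_idx],
    })
    long["is_over"] = long["flag"].to_numpy() == "over"
    long["is_under"] = long["flag"].to_numpy() == "under"
    keys = ["chromosome", "win_start"]
    agg = long.groupby(keys, sort=True).agg(
        n=("symbol", "size"),
        mean_A=("value_A", "mean"),
        mean_B=("value_B", "mean"),
        k_over=("is_over", "sum"),
        k_under=("is_under", "sum"),
        members=("symbol", list),
    ).reset_index()
    for tail in ("over", "under"):
        flagged = long[long[f"is_{tail}"]].groupby(keys)["symbol"].agg(list)
        col = flagged.reindex(
            pd.MultiIndex.from_frame(agg[keys]), fill_value=None
        ).to_numpy()
        agg[f"flagged_{tail}"] = [x if isinstance(x, list) else [] for x in col]
    agg = agg.rename(columns={"win_start": "start"})
    agg["end"] = agg["start"] + window - 1
    return agg


def _choose_call(row, q_threshold: float, min_k: int) -> str:
    over_ok = row["q_over"] < q_threshold and row["k_over"] >= min_k
    under_ok = row["q_under"] < q_threshold and row["k_under"] >= min_k
    if over_ok and under_ok:
        if row["q_over"] != row["q_under"]:
            return "over" if row["q_over"] < row["q_under"] else "under"
        return "over" if row["ratio"] >= 1.0 else "under"
    if over_ok:
        return "over"
    if under_ok:
        return "under"
    return "none"


def _dedup_calls(seg: pd.DataFrame) -> pd.DataFrame:
    """Drop overlapping calls sharing > 50% of the smaller flagged-gene set.

    Among competing calls the lowest q wins; ties go to the larger
    |log ratio|.  Dropped rows keep their statistics but are demoted to
    ``call = none`` with ``dedup_dropped = True``.
    """
    seg = seg.copy()
    seg["dedup_dropped"] = False
    called = seg.index[seg["call"] != "none"]
    if len(called) == 0:
        return seg

    def call_q(i):
        return seg.at[i, "q_over"] if seg.at[i, "call"] == "over" \
            else seg.at[i, "q_under"]

    def flagged_set(i):
        col = "flagged_over" if seg.at[i, "call"] == "over" else "flagged_under"
        return set(seg.at[i, col])

    order = sorted(
        called, key=lambda i: (call_q(i), -abs(math.log(seg.at[i, "ratio"])))
    )
    kept: list[int] = []
    for i in order:
        si = flagged_set(i)
        duplicate = False
        for j in kept:
            if seg.at[i, "chromosome"] != seg.at[j, "chromosome"]:
                continue
            sj = flagged_set(j)
            shared = len(si & sj)
            if shared > 0.5 * min(len(si), len(sj)):
                duplicate = True
                break
        if duplicate:
            seg.at[i, "call"] = "none"
            seg.at[i, "dedup_dropped"] = True
        else:
            kept.append(i)
    return seg


def call_segments(
    entries: pd.DataFrame, windows: pd.DataFrame, params: MapParams | None = None
) -> pd.DataFrame:
    """Score every occupied window for extreme-gene enrichment and call it.

    For each window and each tail the hypergeometric upper-tail p-value is
    computed from (N loci with ratios, K flagged, n in window, k flagged in
    window); q-values correct the full family of window x tail tests; a call
    requires q below the threshold AND at least ``min_extreme_genes`` flagged
    members.  Overlapping calls with mostly-shared flagged genes are
    deduplicated.  The segment ratio is the ratio of member means (mean of
    member A-values over mean of member B-values).
    """
    if params is None:
        params = MapParams()
    window = int(windows["end"].iloc[0] - windows["start"].iloc[0] + 1) \
        if len(windows) else params.window
    agg = _aggregate_windows(entries, window, params.shift)
    # restrict to windows present in the provided grid
    grid = windows[["chromosome", "start"]].drop_duplicates()
    agg = agg.merge(grid, on=["chromosome", "start"], how="inner")
    if agg.empty:
        agg = agg.assign(ratio=[], p_over=[], p_under=[], q_over=[],
                         q_under=[], call=[], dedup_dropped=[])
        return agg

    N = len(entries)
    K_over = int((entries["flag"] == "over").sum())
    K_under = int((entries["flag"] == "under").sum())
    n = agg["n"].to_numpy()
    agg["ratio"] = agg["mean_A"].to_numpy() / agg["mean_B"].to_numpy()
    agg["p_over"] = hypergeom.sf(agg["k_over"].to_numpy() - 1, N, K_over, n)
    agg["p_under"] = hypergeom.sf(agg["k_under"].to_numpy() - 1, N, K_under, n)

    q = correct_q(
        np.concatenate([agg["p_over"].to_numpy(), agg["p_under"].to_numpy()]),
        method=params.correction,
    )
    agg["q_over"] = q[: len(agg)]
    agg["q_under"] = q[len(agg):]

    agg["call"] = agg.apply(
        _choose_call, axis=1, q_threshold=params.q_threshold,
        min_k=params.min_extreme_genes,
    )
    agg = _dedup_calls(agg)

    called = agg[agg["call"] != "none"]
    k_called = np.where(
        called["call"] == "over", called["k_over"], called["k_under"]
    )
    assert (k_called >= params.min_extreme_genes).all()
    return agg.sort_values(["chromosome", "start"], ignore_index=True)


def single_gene_map(
    entries: pd.DataFrame,
    annotation: Sequence[LocusAnnotation] | None = None,
    params: MapParams | None = None,
) -> pd.DataFrame:
    """Per-locus significance calls from the fine-grained window map.

    Windows of ``gene_window`` bp (shift = half window) are tested exactly
    like segments but with a 1-gene minimum.  When a significant window
    holds more than one locus, the call attaches to the flagged locus only
    if its pooled value, in the pool where it is higher, strictly exceeds
    every co-member's value there (the "prevail" rule); otherwise the call
    is dropped and reported with ``maintained = False``.
    """
    if params is None:
        params = MapParams()
    if annotation is not None and "chromosome" not in entries.columns:
        entries = annotate_entries(entries, annotation)
    gw = params.gene_window
    shift = max(1, gw // 2)
    agg = _aggregate_windows(entries, gw, shift)
    if agg.empty:
        return pd.DataFrame(columns=[
            "symbol", "chromosome", "start", "direction", "q",
            "window_start", "window_end", "maintained",
        ])

    N = len(entries)
    K_over = int((entries["flag"] == "over").sum())
    K_under = int((entries["flag"] == "under").sum())
    n = agg["n"].to_numpy()
    p_over = hypergeom.sf(agg["k_over"].to_numpy() - 1, N, K_over, n)
    p_under = hypergeom.sf(agg["k_under"].to_numpy() - 1, N, K_under, n)
    q = correct_q(np.concatenate([p_over, p_under]), method=params.correction)
    agg["q_over"] = q[: len(agg)]
    agg["q_under"] = q[len(agg):]

    values = entries.set_index("symbol")[["value_A", "value_B", "chromosome", "start"]]
    records: list[dict] = []
    candidate = agg[
        ((agg["q_over"] < params.q_threshold) & (agg["k_over"] >= 1))
        | ((agg["q_under"] < params.q_threshold) & (agg["k_under"] >= 1))
    ]
    for _, row in candidate.iterrows():
        for tail in ("over", "under"):
            qv = row[f"q_{tail}"]
            flagged = row[f"flagged_{tail}"]
            if qv >= params.q_threshold or len(flagged) < 1:
                continue
            for symbol in flagged:
                va = values.at[symbol, "value_A"]
                vb = values.at[symbol, "value_B"]
                side = "value_A" if va >= vb else "value_B"
                maintained = True
                if row["n"] > 1:
                    others = [m for m in row["members"] if m != symbol]
                    own = values.at[symbol, side]
                    maintained = all(own > values.at[m, side] for m in others)
                records.append({
                    "symbol": symbol,
                    "chromosome": values.at[symbol, "chromosome"],
                    "start": int(values.at[symbol, "start"]),
                    "direction": tail,
                    "q": float(qv),
                    "window_start": int(row["start"]),
                    "window_end": int(row["end"]),
                    "maintained": bool(maintained),
                })
    if not records:
        return pd.DataFrame(columns=[
            "symbol", "chromosome", "start", "direction", "q",
            "window_start", "window_end", "maintained",
        ])
    rec = pd.DataFrame.from_records(records)
    # one row per locus x direction: prefer maintained calls, then lowest q
    rec = rec.sort_values(
        ["symbol", "direction", "maintained", "q"],
        ascending=[True, True, False, True],
    )
    out = rec.groupby(["symbol", "direction"], as_index=False).first()
    return out.sort_values(["q", "symbol"], ignore_index=True)


def chromosome_medians(entries: pd.DataFrame) -> pd.DataFrame:
    """Median A/B ratio per chromosome (midpoint convention for even counts)."""
    if entries.empty:
        raise ValidationError("chromosome_medians: no entries")
    if "chromosome" not in entries.columns:
        raise ValidationError("entries must be annotated with chromosomes")
    g = entries.groupby("chromosome", sort=True)["ratio"]
    out = pd.DataFrame({
        "chromosome": g.median().index,
        "median_ratio": g.median().to_numpy(),
        "n_loci": g.size().to_numpy(),
    })
    return out.reset_index(drop=True)


def top_genes(
    entries: pd.DataFrame, min_data_points: int = 5, count: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked most over- and under-expressed genes.

    Only loci with at least ``min_data_points`` data points in *both* pools
    are eligible.  Returns ``(over, under)`` sorted by descending and
    ascending ratio respectively.
    """
    eligible = entries[
        (entries["n_points_A"] >= min_data_points)
        & (entries["n_points_B"] >= min_data_points)
    ]
    over = eligible.sort_values("ratio", ascending=False).head(count)
    under = eligible.sort_values("ratio", ascending=True).head(count)
    return over.reset_index(drop=True), under.reset_index(drop=True)
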