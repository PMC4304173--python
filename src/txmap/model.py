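"""Model-style front end: build a differential map from data, ``fit()`` it.

:class:`DifferentialTranscriptomeMap` holds the inputs of one two-pool
comparison (probe-level sample datasets, probe maps, locus annotation,
parameters); :meth:`~DifferentialTranscriptomeMap.fit` runs the full chain

    decode -> linearize -> zero substitution -> percent-of-mean ->
    scaled quantile normalization (all samples jointly) -> pooling ->
    per-locus ratios -> extreme flags -> segment / single-gene /
    chromosome maps -> ranked gene lists

and returns a :class:`DifferentialMapResults` carrying every table, the
bookkeeping counts and a ``summary()`` rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mapping, normalization, pooling
from .errors import PipelineError, ValidationError
from .io import LocusAnnotation, ProbeAssignment, SampleDataset, decode_probes
from .mapping import MapParams
from .normalization import NormalizationParams
from .pooling import PoolExpression

__all__ = ["DifferentialTranscriptomeMap", "DifferentialMapResults"]


class DifferentialTranscriptomeMap:
    """Differential transcriptome map of pool A versus pool B.

    Parameters
    ----------
    datasets
        Probe-level sample datasets (any pools; only the two compared pools
        are used).
    probe_maps
        Probe→locus assignments covering every dataset's platform.
    annotation
        Locus annotation providing genomic coordinates.
    pool_a, pool_b
        The two pool identifiers to compare (ratios are A/B).
    map_params, norm_params
        Windowing/calling and normalization parameters; defaults follow the
        method's standard settings (500 kb / 250 kb windows, 2.5% tails,
        q < 0.05, >= 3 extreme genes, >= 5 data points, 95% zero
        substitution).
    strict_probes
        If True, a dataset probe absent from the probe map is an error;
        otherwise it is skipped with a logged count.
    """

    def __init__(
        self,
        datasets: Sequence[SampleDataset],
        probe_maps: Sequence[ProbeAssignment],
        annotation: Sequence[LocusAnnotation],
        pool_a: str,
        pool_b: str,
        map_params: MapParams | None = None,
        norm_params: NormalizationParams | None = None,
        strict_probes: bool = False,
    ):
        self.datasets = list(datasets)
        self.probe_maps = list(probe_maps)
        self.annotation = list(annotation)
        self.pool_a = pool_a
        self.pool_b = pool_b
        self.map_params = map_params or MapParams()
        self.norm_params = norm_params or NormalizationParams()
        self.strict_probes = strict_probes

        symbols = [a.symbol for a in self.annotation]
        if len(symbols) != len(set(symbols)):
            dupe = next(s for s in symbols if symbols.count(s) > 1)
            raise ValidationError(f"annotation has duplicate symbol {dupe!r}")
        pools = {d.pool_id for d in self.datasets}
        for pool in (pool_a, pool_b):
            if pool not in pools:
                raise ValidationError(f"no datasets for pool {pool!r}")
        platforms = {d.platform_id for d in self.datasets
                     if d.pool_id in (pool_a, pool_b)}
        mapped = {a.platform_id for a in self.probe_maps}
        unmapped_platforms = platforms - mapped
        if unmapped_platforms:
            raise ValidationError(
                f"no probe map for platform(s) {sorted(unmapped_platforms)}"
            )

    @classmethod
    def from_study(cls, study, pool_a: str = "A", pool_b: str = "B", **kwargs):
        """Build directly from a :class:`~txmap.simulate.SimulatedStudy`."""
        return cls(study.datasets, study.probe_assignments, study.annotation,
                   pool_a, pool_b, **kwargs)

    @classmethod
    def from_config(cls, config):
        """Build from a loaded :class:`~txmap.config.RunConfig`."""
        return config.build_model()

    # ------------------------------------------------------------------ fit

    def fit(self) -> "DifferentialMapResults":
        """Run the full comparison and return the results object."""
        used = [d for d in self.datasets
                if d.pool_id in (self.pool_a, self.pool_b)]

        # decode each sample's probes to per-locus data points
        try:
            decoded = [decode_probes(d, self.probe_maps, strict=self.strict_probes)
                       for d in used]
        except ValidationError as exc:
            raise PipelineError("decode", str(exc)) from exc

        # per-sample normalization chain on the flattened point values
        sample_symbols: list[np.ndarray] = []
        sample_values: list[np.ndarray] = []
        try:
            for ds, points in zip(used, decoded):
                syms = np.array([ldp.symbol for ldp in points
                                 for _ in ldp.points])
                vals = np.array([v for ldp in points for _, v in ldp.points])
                if vals.size == 0:
                    raise ValidationError(
                        f"sample {ds.sample_id}: no mapped measured probes"
                    )
                vals = normalization.linearize(vals, ds.scale)
                vals = normalization.replace_nonpositive(
                    vals, self.norm_params.nonpositive_factor
                )
                vals = normalization.normalize_intra(vals)
                sample_symbols.append(syms)
                sample_values.append(vals)
            normalized = normalization.scaled_quantile_normalize(
                sample_values, self.norm_params
            )
        except ValidationError as exc:
            raise PipelineError("normalize", str(exc)) from exc

        # pool the normalized points per condition
        try:
            frames = {
                self.pool_a: [], self.pool_b: [],
            }
            for ds, syms, vals in zip(used, sample_symbols, normalized):
                frames[ds.pool_id].append(
                    pd.DataFrame({"symbol": syms, "value": vals})
                )
            pool_a = pooling.pool_frame(
                pd.concat(frames[self.pool_a], ignore_index=True), self.pool_a
            )
            pool_b = pooling.pool_frame(
                pd.concat(frames[self.pool_b], ignore_index=True), self.pool_b
            )
        except ValidationError as exc:
            raise PipelineError("pool", str(exc)) from exc

        # differential map
        try:
            entries = mapping.compute_differential(pool_a, pool_b)
            entries = mapping.annotate_entries(entries, self.annotation)
            entries = mapping.flag_extremes(entries, self.map_params.tail)
            windows = mapping.build_windows(
                self.annotation, self.map_params.window, self.map_params.shift
            )
            segments = mapping.call_segments(entries, windows, self.map_params)
            gene_calls = mapping.single_gene_map(entries, params=self.map_params)
            chromosomes = mapping.chromosome_medians(entries)
            over, under = mapping.top_genes(
                entries, self.map_params.min_data_points
            )
            corr_r, corr_p = pooling.compute_pool_correlation(pool_a, pool_b)
        except ValidationError as exc:
            raise PipelineError("map", str(exc)) from exc

        counts = {
            f"data_points_{self.pool_a}": pool_a.total_data_points,
            f"data_points_{self.pool_b}": pool_b.total_data_points,
            f"loci_{self.pool_a}": pool_a.n_loci,
            f"loci_{self.pool_b}": pool_b.n_loci,
            "shared_loci": len(entries),
            "flagged_over": int((entries["flag"] == "over").sum()),
            "flagged_under": int((entries["flag"] == "under").sum()),
            "windows": len(windows),
            "windows_tested": len(segments),
            "segments_called": int((segments["call"] != "none").sum()),
        }
        return DifferentialMapResults(
            model=self,
            pool_a=pool_a,
            pool_b=pool_b,
            entries=entries,
            windows=windows,
            segments=segments,
            gene_calls=gene_calls,
            chromosomes=chromosomes,
            top_over=over,
            top_under=under,
            pool_correlation=(corr_r, corr_p),
            counts=counts,
        )


@dataclass
class DifferentialMapResults:
    """Fitted differential transcriptome map.

    Attributes
    ----------
    entries : DataFrame
        Per-locus table: pooled means, ratio, counts, SD%, extreme flag,
        coordinates.
    segments : DataFrame
        Per-window statistics and calls (500-kb map).
    gene_calls : DataFrame
        Single-gene map calls (12.5-kb windows, prevail rule applied).
    chromosomes : DataFrame
        Per-chromosome median ratio and locus count.
    top_over, top_under : DataFrame
        Ranked gene lists among loci with enough data points.
    pool_correlation : (r, p)
        Pearson correlation of log10 pooled means over shared loci.
    counts : dict
        Bookkeeping: data points and loci per pool, shared loci, flagged
        counts, window counts, called segments.
    """

    model: DifferentialTranscriptomeMap
    pool_a: PoolExpression
    pool_b: PoolExpression
    entries: pd.DataFrame
    windows: pd.DataFrame
    segments: pd.DataFrame
    gene_calls: pd.DataFrame
    chromosomes: pd.DataFrame
    top_over: pd.DataFrame
    top_under: pd.DataFrame
    pool_correlation: tuple[float, float]
    counts: dict = field(default_factory=dict)

    @property
    def called_segments(self) -> pd.DataFrame:
        return self.segments[self.segments["call"] != "none"].reset_index(drop=True)

    # ------------------------------------------------------------- summary

    def summary(self, top: int = 5) -> str:
        """Human-readable run summary (deterministic, no timestamps)."""
        m = self.model
        p = m.map_params
        lines = [
            "Differential transcriptome map",
            "=" * 62,
            f"comparison        : pool {m.pool_a} vs pool {m.pool_b} "
            f"(ratios are {m.pool_a}/{m.pool_b})",
            f"window / shift    : {p.window:,} / {p.shift:,} bp "
            f"(gene window {p.gene_window:,} bp)",
            f"tails / q / min k : {p.tail:g} each side, q < {p.q_threshold:g}, "
            f">= {p.min_extreme_genes} extreme genes "
            f"({p.correction.upper()} correction)",
            "-" * 62,
        ]
        for key, val in self.counts.items():
            lines.append(f"{key:<22}: {val:,}")
        r, pv = self.pool_correlation
        lines.append(f"{'pool correlation r':<22}: {r:.4f} (p = {pv:.3g})")
        lines.append("-" * 62)
        called = self.called_segments
        lines.append(f"called segments ({len(called)}):")
        for _, s in called.head(top).iterrows():
            q = s["q_over"] if s["call"] == "over" else s["q_under"]
            lines.append(
                f"  {s['chromosome']}:{s['start']:,}-{s['end']:,}  "
                f"{s['call']:<5} ratio={s['ratio']:.2f} q={q:.2e} "
                f"k={s['k_over'] if s['call'] == 'over' else s['k_under']}"
            )
        lines.append("chromosome medians (extremes):")
        chrom = self.chromosomes.sort_values("median_ratio")
        shown = pd.concat([chrom.head(2), chrom.tail(2)]).drop_duplicates()
        for _, c in shown.iterrows():
            lines.append(
                f"  {c['chromosome']:<8} median ratio {c['median_ratio']:.3f} "
                f"(n = {int(c['n_loci'])})"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------- reports

    def to_directory(self, output_dir: str | Path, force: bool = False) -> Path:
        """Write the report bundle: segment, gene, chromosome tables + log."""
        out = Path(output_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise ValidationError(
                f"output directory {out} is not empty (use force to overwrite)"
            )
        out.mkdir(parents=True, exist_ok=True)
        ff = lambda df: df.to_csv(index=False, sep="\t", float_format="%.6g")

        seg = self.segments.copy()
        for col in ("members", "flagged_over", "flagged_under"):
            seg[col] = seg[col].map(";".join)
        (out / "segments.tsv").write_text(ff(seg), encoding="utf-8")
        (out / "genes_over.tsv").write_text(ff(self.top_over), encoding="utf-8")
        (out / "genes_under.tsv").write_text(ff(self.top_under), encoding="utf-8")
        (out / "genes_single.tsv").write_text(ff(self.gene_calls), encoding="utf-8")
        (out / "chromosomes.tsv").write_text(ff(self.chromosomes), encoding="utf-8")
        (out / "entries.tsv").write_text(ff(self.entries), encoding="utf-8")
        (out / "run.log").write_text(self.run_log(), encoding="utf-8")
        return out

    def run_log(self) -> str:
        """Parameter and bookkeeping log (byte-stable across re-runs)."""
        m = self.model
        lines = ["# txmap run log", "## parameters"]
        for name, obj in (("map", m.map_params), ("normalization", m.norm_params)):
            for key, val in vars(obj).items():
                lines.append(f"{name}.{key} = {val}")
        lines.append(f"strict_probes = {m.strict_probes}")
        lines.append(f"pools = {m.pool_a},{m.pool_b}")
        lo, hi = self.entries.attrs.get("ratio_thresholds", (float("nan"),) * 2)
        lines.append(f"ratio_thresholds = {lo:.6g},{hi:.6g}")
        lines.append("## counts")
        for key, val in self.counts.items():
            lines.append(f"{key} = {val}")
        r, pv = self.pool_correlation
        lines.append(f"pool_correlation_r = {r:.6g}")
        lines.append(f"pool_correlation_p = {pv:.6g}")
        return "\n".join(lines) + "\n"

    def plot_chromosome(self, chromosome: str, ax=None):
        """Scatter of per-locus log2 ratios along one chromosome with called
        segments shaded.  Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        sub = self.entries[self.entries["chromosome"] == chromosome]
        ax.scatter(sub["start"] / 1e6, np.log2(sub["ratio"]), s=6, alpha=0.5)
        for _, s in self.called_segments.iterrows():
            if s["chromosome"] != chromosome:
                continue
            color = "tab:red" if s["call"] == "over" else "tab:blue"
            ax.axvspan(s["start"] / 1e6, s["end"] / 1e6, alpha=0.2, color=color)
        ax.axhline(0.0, lw=0.8, color="k")
        ax.set_xlabel(f"{chromosome} position (Mb)")
        ax.set_ylabel("log2 ratio A/B")
        return ax
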