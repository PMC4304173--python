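"""Synthetic multi-platform expression studies with known ground truth.

The generator emulates the statistical structure of pooled public
microarray studies: several platforms with different probe counts and
partially overlapping gene coverage, one to three probes per covered locus,
per-platform intensity scale offsets, multiplicative log-normal measurement
noise, a small rate of missing and non-positive values, some deposits on a
log2 scale, and three kinds of true differential signal —

* a *dosage chromosome* whose loci are expressed at a constant factor
  (default 1.5, the expectation for a trisomic chromosome) in designated
  pools;
* *injected segments*: clusters of co-regulated loci inside one genomic
  window, over- or under-expressed by a fold factor in designated pools;
* *sex-biased loci*: single loci with a large fold difference between
  designated pools.

Everything is driven by one recorded seed; fixtures written to disk are
byte-identical across re-runs with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .io import (
    UNMAPPED,
    LocusAnnotation,
    ProbeAssignment,
    SampleDataset,
    write_annotation,
    write_probe_map,
    write_sample_matrix,
)

__all__ = [
    "PlatformSpec",
    "InjectedSegment",
    "SexBiasedLocus",
    "SyntheticTruth",
    "SimulatedStudy",
    "generate_annotation",
    "default_truth",
    "generate_pools",
    "simulate_study",
    "write_fixture",
]


@dataclass(frozen=True)
class PlatformSpec:
    """One simulated array platform."""

    platform_id: str
    coverage: float = 1.0          # fraction of loci the platform measures
    min_probes: int = 1            # probes per covered locus (inclusive range)
    max_probes: int = 3
    scale: str = "linear"          # deposit scale: linear or log2
    control_fraction: float = 0.01  # extra unmapped control probes

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValidationError("platform coverage must be in (0, 1]")
        if not (1 <= self.min_probes <= self.max_probes):
            raise ValidationError("need 1 <= min_probes <= max_probes")
        if self.scale not in ("linear", "log2"):
            raise ValidationError("platform scale must be linear or log2")


@dataclass(frozen=True)
class InjectedSegment:
    """A cluster of co-regulated loci inside one genomic window."""

    chromosome: str
    start: int
    end: int
    symbols: tuple[str, ...]
    fold: float = 10.0
    direction: str = "over"
    pools: tuple[str, ...] = ("A",)


@dataclass(frozen=True)
class SexBiasedLocus:
    symbol: str
    fold: float
    pools: tuple[str, ...] = ("A",)


@dataclass
class SyntheticTruth:
    """Full specification of a synthetic study; the single seed drives it."""

    annotation: list[LocusAnnotation]
    platforms: list[PlatformSpec]
    injected_segments: list[InjectedSegment] = field(default_factory=list)
    dosage_chromosome: str | None = None
    dosage_factor: float = 1.5
    trisomic_pools: tuple[str, ...] = ("A",)
    sex_biased: list[SexBiasedLocus] = field(default_factory=list)
    noise_sigma: float = 0.2            # ln-scale SD of per-point noise
    platform_offset_sigma: float = 0.5  # ln-scale SD of platform scale offsets
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    missing_rate: float = 0.02
    nonpositive_rate: float = 0.01      # linear-scale platforms only
    seed: int = 0

    def validate(self) -> None:
        symbols = {a.symbol for a in self.annotation}
        if len(symbols) != len(self.annotation):
            raise ValidationError("annotation has duplicate symbols")
        for seg in self.injected_segments:
            if seg.fold <= 0:
                raise ValidationError("injected fold must be > 0")
            for s in seg.symbols:
                if s not in symbols:
                    raise ValidationError(f"injected symbol {s!r} not annotated")
        for sb in self.sex_biased:
            if sb.fold <= 0:
                raise ValidationError("sex-bias fold must be > 0")
            if sb.symbol not in symbols:
                raise ValidationError(f"sex-biased symbol {sb.symbol!r} not annotated")
        if self.dosage_factor <= 0:
            raise ValidationError("dosage factor must be > 0")
        if not self.platforms:
            raise ValidationError("at least one platform required")

    def pool_fold(self, pool_id: str) -> np.ndarray:
        """True expression fold of every locus in ``pool_id`` vs baseline."""
        n = len(self.annotation)
        idx = {a.symbol: i for i, a in enumerate(self.annotation)}
        fold = np.ones(n)
        if self.dosage_chromosome is not None and pool_id in self.trisomic_pools:
            for i, a in enumerate(self.annotation):
                if a.chromosome == self.dosage_chromosome:
                    fold[i] *= self.dosage_factor
        for seg in self.injected_segments:
            if pool_id in seg.pools:
                f = seg.fold if seg.direction == "over" else 1.0 / seg.fold
                for s in seg.symbols:
                    fold[idx[s]] *= f
        for sb in self.sex_biased:
            if pool_id in sb.pools:
                fold[idx[sb.symbol]] *= sb.fold
        return fold

    def truth_table(self):
        """Ground-truth table: symbol, chromosome, effect type, fold, pools."""
        import pandas as pd

        rows = []
        tagged: set[str] = set()
        for seg in self.injected_segments:
            for s in seg.symbols:
                fold = seg.fold if seg.direction == "over" else 1.0 / seg.fold
                rows.append((s, seg.chromosome, "segment", fold,
                             ",".join(seg.pools)))
                tagged.add(s)
        for sb in self.sex_biased:
            chrom = next(a.chromosome for a in self.annotation
                         if a.symbol == sb.symbol)
            rows.append((sb.symbol, chrom, "sex", sb.fold, ",".join(sb.pools)))
            tagged.add(sb.symbol)
        for a in self.annotation:
            if a.symbol in tagged:
                continue
            if self.dosage_chromosome is not None \
                    and a.chromosome == self.dosage_chromosome:
                rows.append((a.symbol, a.chromosome, "dosage",
                             self.dosage_factor, ",".join(self.trisomic_pools)))
            else:
                rows.append((a.symbol, a.chromosome, "null", 1.0, ""))
        return pd.DataFrame(
            rows, columns=["symbol", "chromosome", "effect_type", "fold", "pools"]
        )


@dataclass
class SimulatedStudy:
    """In-memory result of :func:`generate_pools`."""

    truth: SyntheticTruth
    datasets: list[SampleDataset]
    probe_assignments: list[ProbeAssignment]
    pool_sizes: dict[str, int]

    @property
    def annotation(self) -> list[LocusAnnotation]:
        return self.truth.annotation


def generate_annotation(
    n_chromosomes: int,
    loci_per_chromosome: int,
    chromosome_extent: int,
    seed: int,
    chromosome_names: Sequence[str] | None = None,
    prefix: str = "G",
) -> list[LocusAnnotation]:
    """Place loci uniformly at random on equal-extent chromosomes.

    Locus spans are log-normal (median ~20 kb, capped at 200 kb).  About one
    locus in ten receives an EST-cluster-style ``Hs.`` identifier.
    Deterministic given the seed.
    """
    if n_chromosomes < 1 or loci_per_chromosome < 1:
        raise ValidationError("chromosome and locus counts must be positive")
    if chromosome_extent < 10 * loci_per_chromosome:
        raise ValidationError(
            f"extent {chromosome_extent} too small for {loci_per_chromosome} loci"
        )
    if chromosome_names is None:
        chromosome_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    rng = np.random.default_rng(seed)
    out: list[LocusAnnotation] = []
    counter = 0
    for chrom in chromosome_names:
        starts = np.sort(rng.integers(1, chromosome_extent, loci_per_chromosome))
        lengths = np.minimum(
            np.exp(rng.normal(math.log(20_000), 1.0, loci_per_chromosome)),
            200_000,
        ).astype(np.int64) + 1
        est = rng.random(loci_per_chromosome) < 0.1
        for j in range(loci_per_chromosome):
            counter += 1
            symbol = (f"Hs.{prefix}{counter:05d}" if est[j]
                      else f"{prefix}{counter:05d}")
            start = int(starts[j])
            end = min(start + int(lengths[j]) - 1, chromosome_extent)
            out.append(LocusAnnotation(symbol, chrom, start, end))
    return out


_DEFAULT_PLATFORMS = (
    PlatformSpec("SIM-W1", coverage=1.00, min_probes=1, max_probes=3,
                 scale="linear"),
    PlatformSpec("SIM-W2", coverage=0.80, min_probes=1, max_probes=3,
                 scale="log2"),
    PlatformSpec("SIM-W3", coverage=0.60, min_probes=1, max_probes=2,
                 scale="linear"),
)


def default_truth(
    seed: int,
    *,
    null: bool = False,
    n_null_chromosomes: int = 3,
    loci_per_chromosome: int = 1700,
    chromosome_extent: int = 50_000_000,
    dosage_loci: int = 300,
    dosage_extent: int = 10_000_000,
    dosage_factor: float = 1.5,
    segment_fold: float = 10.0,
    segment_size: int = 6,
    noise_sigma: float = 0.2,
    platforms: Sequence[PlatformSpec] = _DEFAULT_PLATFORMS,
) -> SyntheticTruth:
    """The package's reference study conditions.

    Three 50-Mb background chromosomes with 1,700 loci each plus, unless
    ``null``, a 10-Mb dosage chromosome carrying 300 loci at 1.5x in pool A,
    one 6-gene 10x over-expressed cluster inside a 500-kb window of chr2,
    and two sex-biased loci.  ``null`` drops every injected effect (the
    background geometry is kept).
    """
    annotation = generate_annotation(
        n_null_chromosomes, loci_per_chromosome, chromosome_extent, seed
    )
    injected: list[InjectedSegment] = []
    sex_biased: list[SexBiasedLocus] = []
    dosage_chrom: str | None = None

    rng = np.random.default_rng((seed, 101))
    if not null:
        dosage_chrom = f"chr{n_null_chromosomes + 1}"
        annotation = annotation + generate_annotation(
            1, dosage_loci, dosage_extent, seed + 1,
            chromosome_names=[dosage_chrom], prefix="D",
        )
        # relocate a random handful of chr2 loci into one 500-kb window
        chr2 = [a for a in annotation if a.chromosome == "chr2"]
        chosen = rng.choice(len(chr2), size=segment_size, replace=False)
        cluster_start = 10_000_001
        members: list[str] = []
        for j, ci in enumerate(sorted(chosen)):
            old = chr2[ci]
            start = cluster_start + j * 80_000
            moved = LocusAnnotation(old.symbol, old.chromosome,
                                    start, start + 20_000, old.cytoband)
            annotation[annotation.index(old)] = moved
            members.append(old.symbol)
        injected.append(InjectedSegment(
            "chr2", cluster_start, cluster_start + 499_999,
            tuple(members), fold=segment_fold, direction="over", pools=("A",),
        ))
        # sex-biased loci on the last background chromosome
        pool_a_biased = [a for a in annotation
                         if a.chromosome == f"chr{n_null_chromosomes}"
                         and a.symbol not in members]
        picks = rng.choice(len(pool_a_biased), size=2, replace=False)
        sex_biased = [
            SexBiasedLocus(pool_a_biased[int(picks[0])].symbol, 30.0, ("A",)),
            SexBiasedLocus(pool_a_biased[int(picks[1])].symbol, 5.0, ("A",)),
        ]

    truth = SyntheticTruth(
        annotation=annotation,
        platforms=list(platforms),
        injected_segments=injected,
        dosage_chromosome=dosage_chrom,
        dosage_factor=dosage_factor,
        trisomic_pools=("A",),
        sex_biased=sex_biased,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    truth.validate()
    return truth


def generate_pools(
    truth: SyntheticTruth, pool_sizes: dict[str, int]
) -> SimulatedStudy:
    """Draw probe-level sample datasets for every pool.

    Each sample is assigned a platform round-robin; each probe value is
    baseline x pool fold x platform offset x log-normal noise, after which
    the stated fractions of values are set missing or to zero (linear
    platforms only), and log2 platforms deposit log2 values.
    """
    truth.validate()
    for pool, size in pool_sizes.items():
        if size < 1:
            raise ValidationError(f"pool {pool!r} size must be >= 1")
    rng = np.random.default_rng((truth.seed, 7))
    ann = truth.annotation
    n_loci = len(ann)

    baseline = np.exp(rng.normal(truth.baseline_log_mean,
                                 truth.baseline_log_sd, n_loci))

    # platform structures: covered loci, probes per locus, scale offset
    assignments: list[ProbeAssignment] = []
    platform_probe_locus: dict[str, tuple[list[str], np.ndarray]] = {}
    platform_offset: dict[str, float] = {}
    for spec in truth.platforms:
        n_cov = max(1, round(spec.coverage * n_loci))
        covered = np.sort(rng.choice(n_loci, size=n_cov, replace=False))
        n_probes = rng.integers(spec.min_probes, spec.max_probes + 1, n_cov)
        probe_ids: list[str] = []
        locus_idx = np.repeat(covered, n_probes)
        for j in range(locus_idx.size):
            probe_ids.append(f"{spec.platform_id}:p{j + 1:06d}")
        n_ctrl = round(spec.control_fraction * len(probe_ids))
        ctrl_ids = [f"{spec.platform_id}:ctrl{j + 1:04d}" for j in range(n_ctrl)]
        for pid, li in zip(probe_ids, locus_idx):
            assignments.append(
                ProbeAssignment(spec.platform_id, pid, ann[int(li)].symbol)
            )
        for cid in ctrl_ids:
            assignments.append(ProbeAssignment(spec.platform_id, cid, UNMAPPED))
        platform_probe_locus[spec.platform_id] = (probe_ids + ctrl_ids, locus_idx)
        platform_offset[spec.platform_id] = float(
            np.exp(rng.normal(0.0, truth.platform_offset_sigma))
        )

    spec_by_id = {s.platform_id: s for s in truth.platforms}
    datasets: list[SampleDataset] = []
    for pool in sorted(pool_sizes):
        fold = truth.pool_fold(pool)
        for i in range(pool_sizes[pool]):
            spec = truth.platforms[i % len(truth.platforms)]
            probe_ids, locus_idx = platform_probe_locus[spec.platform_id]
            n_mapped = locus_idx.size
            n_total = len(probe_ids)
            signal = (baseline[locus_idx] * fold[locus_idx]
                      * platform_offset[spec.platform_id]
                      * np.exp(rng.normal(0.0, truth.noise_sigma, n_mapped)))
            ctrl = np.exp(rng.normal(truth.baseline_log_mean, 1.0,
                                     n_total - n_mapped))
            values = np.concatenate([signal, ctrl])
            if spec_by_id[spec.platform_id].scale == "linear":
                zero_mask = rng.random(n_total) < truth.nonpositive_rate
                values[zero_mask] = 0.0
            missing_mask = rng.random(n_total) < truth.missing_rate
            values[missing_mask] = np.nan
            if spec_by_id[spec.platform_id].scale == "log2":
                values = np.log2(values)
            datasets.append(SampleDataset(
                sample_id=f"{pool}{i + 1:02d}",
                pool_id=pool,
                platform_id=spec.platform_id,
                values=dict(zip(probe_ids, values.tolist())),
                scale=spec_by_id[spec.platform_id].scale,
            ))
    return SimulatedStudy(truth, datasets, assignments, dict(pool_sizes))


def simulate_study(
    seed: int,
    *,
    null: bool = False,
    pool_sizes: dict[str, int] | None = None,
    **truth_kwargs,
) -> SimulatedStudy:
    """Convenience wrapper: default truth + default pool sizes (A=12, B=10)."""
    if pool_sizes is None:
        pool_sizes = {"A": 12, "B": 10}
    truth = default_truth(seed, null=null, **truth_kwargs)
    return generate_pools(truth, pool_sizes)


def write_fixture(
    study: SimulatedStudy,
    output_dir: str | Path,
    force: bool = False,
    compare: tuple[str, str] | None = None,
) -> Path:
    """Write a complete on-disk fixture: annotation, probe map, matrices,
    ground truth and a ready-to-run config.  Byte-identical per seed."""
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out} is not empty (use force to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)

    write_annotation(study.annotation, out / "annotation.tsv")
    write_probe_map(study.probe_assignments, out / "probe_map.tsv")

    dataset_decls = []
    groups: dict[tuple[str, str], list[SampleDataset]] = {}
    for d in study.datasets:
        groups.setdefault((d.pool_id, d.platform_id), []).append(d)
    for (pool, platform), ds in sorted(groups.items()):
        fname = f"matrix_{pool}_{platform.replace(':', '-')}.tsv"
        write_sample_matrix(ds, out / fname)
        dataset_decls.append({
            "path": fname,
            "platform": platform,
            "pool": pool,
            "scale": ds[0].scale,
        })

    study.truth.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)

    pools = sorted(study.pool_sizes)
    if compare is None:
        compare = (pools[0], pools[1]) if len(pools) >= 2 else (pools[0], pools[0])
    config = {
        "annotation": "annotation.tsv",
        "probe_maps": ["probe_map.tsv"],
        "datasets": dataset_decls,
        "compare": list(compare),
        "output": "results",
        "seed": study.truth.seed,
        "params": {},
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out
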