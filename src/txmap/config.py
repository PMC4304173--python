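"""Run configuration: one YAML file describing a full two-pool comparison.

Schema (paths are resolved relative to the config file)::

    annotation: annotation.tsv
    probe_maps: [probe_map.tsv]
    datasets:
      - {path: matrix_A_P1.tsv, platform: P1, pool: A, scale: linear}
      - {path: matrix_B_P1.tsv, platform: P1, pool: B, scale: log2}
    compare: [A, B]
    output: results
    seed: 0
    params:                      # optional overrides, defaults otherwise
      window: 500000
      shift: 250000
      gene_window: 12500
      tail: 0.025
      q_threshold: 0.05
      min_extreme_genes: 3
      min_data_points: 5
      correction: bh
      nonpositive_factor: 0.95
      quantile_grid_size: 1001
      strict_probes: false
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .io import SCALE_TAGS, read_annotation, read_probe_map, read_sample_matrix
from .mapping import MapParams
from .normalization import NormalizationParams

__all__ = ["DatasetDecl", "RunConfig", "load_config"]

_MAP_KEYS = {"window", "shift", "gene_window", "tail", "q_threshold",
             "min_extreme_genes", "min_data_points", "correction"}
_NORM_KEYS = {"nonpositive_factor", "quantile_grid_size"}


@dataclass
class DatasetDecl:
    path: Path
    platform: str
    pool: str
    scale: str = "linear"


@dataclass
class RunConfig:
    annotation: Path
    probe_maps: list[Path]
    datasets: list[DatasetDecl]
    compare: tuple[str, str]
    output: Path
    seed: int = 0
    map_params: MapParams = field(default_factory=MapParams)
    norm_params: NormalizationParams = field(default_factory=NormalizationParams)
    strict_probes: bool = False

    def validate(self) -> None:
        if len(set(self.compare)) != 2:
            raise ConfigError(
                f"compare must name exactly two distinct pools, got {self.compare}"
            )
        pools = {d.pool for d in self.datasets}
        for pool in self.compare:
            if pool not in pools:
                raise ConfigError(f"compared pool {pool!r} has no datasets")
        for d in self.datasets:
            if d.scale not in SCALE_TAGS:
                raise ConfigError(
                    f"dataset {d.path.name}: unknown scale {d.scale!r}"
                )

    def build_model(self):
        """Read every input file and assemble the model object."""
        from .model import DifferentialTranscriptomeMap

        self.validate()
        annotation = read_annotation(self.annotation)
        probe_maps = []
        for pm in self.probe_maps:
            probe_maps.extend(read_probe_map(pm, annotation))
        platforms = {a.platform_id for a in probe_maps}
        datasets = []
        for decl in self.datasets:
            if decl.platform not in platforms:
                raise ConfigError(
                    f"dataset {decl.path.name}: platform {decl.platform!r} "
                    f"has no probe map"
                )
            datasets.extend(
                read_sample_matrix(decl.path, decl.platform, decl.pool, decl.scale)
            )
        return DifferentialTranscriptomeMap(
            datasets, probe_maps, annotation,
            pool_a=self.compare[0], pool_b=self.compare[1],
            map_params=self.map_params, norm_params=self.norm_params,
            strict_probes=self.strict_probes,
        )


def _require(doc: dict, key: str, path: Path):
    if key not in doc:
        raise ConfigError(f"{path}: missing required key {key!r}")
    return doc[key]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load and validate a run configuration file.

    Keyword ``overrides`` replace entries of the ``params`` block (e.g.
    ``window=100000``); unknown parameter names are an error.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    except OSError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent

    raw_datasets = _require(doc, "datasets", path)
    if not isinstance(raw_datasets, list) or not raw_datasets:
        raise ConfigError(f"{path}: 'datasets' must be a non-empty list")
    datasets = []
    for i, entry in enumerate(raw_datasets):
        if not isinstance(entry, dict):
            raise ConfigError(f"{path}: datasets[{i}] must be a mapping")
        for key in ("path", "platform", "pool"):
            if key not in entry:
                raise ConfigError(f"{path}: datasets[{i}] missing {key!r}")
        datasets.append(DatasetDecl(
            path=base / entry["path"],
            platform=str(entry["platform"]),
            pool=str(entry["pool"]),
            scale=str(entry.get("scale", "linear")),
        ))

    compare = _require(doc, "compare", path)
    if not (isinstance(compare, (list, tuple)) and len(compare) == 2):
        raise ConfigError(f"{path}: 'compare' must list exactly two pools")

    params = dict(doc.get("params") or {})
    params.update(overrides)
    unknown = set(params) - _MAP_KEYS - _NORM_KEYS - {"strict_probes"}
    if unknown:
        raise ConfigError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    try:
        map_params = MapParams(**{k: v for k, v in params.items()
                                  if k in _MAP_KEYS})
        norm_params = NormalizationParams(**{k: v for k, v in params.items()
                                             if k in _NORM_KEYS})
    except Exception as exc:
        raise ConfigError(f"{path}: bad parameter value ({exc})") from exc

    cfg = RunConfig(
        annotation=base / str(_require(doc, "annotation", path)),
        probe_maps=[base / str(p) for p in _require(doc, "probe_maps", path)],
        datasets=datasets,
        compare=(str(compare[0]), str(compare[1])),
        output=base / str(doc.get("output", "results")),
        seed=int(doc.get("seed", 0)),
        map_params=map_params,
        norm_params=norm_params,
        strict_probes=bool(params.get("strict_probes", False)),
    )
    cfg.validate()
    return cfg
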