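"""Top-level pipeline: run configured stages and write a report bundle."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .doublets import DoubletModel
from .fluor import classify_experiment
from .io import (
    read_ani_tables,
    read_layout,
    read_plate_table,
    write_json,
)
from .ani import StrainLineageModel
from .layout import default_layout

log = logging.getLogger("scdispense")


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    ``readings`` enables the classify + doublets stages; ``ani`` (with
    optional ``quality``/``refs``) enables the clustering stage. At least one
    stage must be configured.
    """

    out_dir: Path
    readings: Path | None = None
    layout: Path | None = None
    background_roles: tuple[str, ...] = ("ntc",)
    doublet_model: str = "pairwise"
    bootstrap: int = 1000
    seed: int = 0
    ani: Path | None = None
    quality: Path | None = None
    refs: Path | None = None
    strain_ani: float = 99.0
    lineage_ani: float = 99.9
    self_min_af: float = 75.0
    ref_min_af: float = 50.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not doc:
            raise ValueError(f"empty pipeline config: {path}")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {}
        extra = {}
        for k, v in doc.items():
            if k in known:
                kwargs[k] = v
            else:
                extra[k] = v
        if "out_dir" not in kwargs:
            raise ValueError("config must set out_dir")
        for key in ("out_dir", "readings", "layout", "ani", "quality", "refs"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "background_roles" in kwargs:
            kwargs["background_roles"] = tuple(kwargs["background_roles"])
        cfg = cls(extra=extra, **kwargs)
        for key in ("readings", "layout", "ani", "quality", "refs"):
            p = getattr(cfg, key)
            if p is not None and not p.exists():
                raise FileNotFoundError(f"config path {key} does not exist: {p}")
        if cfg.readings is None and cfg.ani is None:
            raise ValueError("config enables no stage: set readings and/or ani")
        for thr in (cfg.strain_ani, cfg.lineage_ani, cfg.self_min_af, cfg.ref_min_af):
            if not (0 <= thr <= 100):
                raise ValueError(f"threshold outside [0, 100]: {thr}")
        return cfg

    def resolved(self) -> dict:
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in self.__dict__.items()}
        d["background_roles"] = list(self.background_roles)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the report dict; writes ``report.json`` plus per-stage tables to
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.resolved(), "stages": {}}

    if config.readings is not None:
        log.info("[classify] reading %s", config.readings)
        layout = read_layout(config.layout) if config.layout else default_layout()
        readings = read_plate_table(config.readings, layout)
        classified, thresholds, counts = classify_experiment(
            readings, layout, background_roles=config.background_roles
        )
        classified.to_csv(out_dir / "classified_wells.tsv", sep="\t", index=False)
        report["stages"]["classify"] = {
            "thresholds": thresholds.to_dict(),
            "signal_counts": counts.to_dict(),
        }
        log.info(
            "[classify] %d non-empty wells, %d dual", counts.n_nonempty, counts.n_dual
        )
        log.info("[doublets] model=%s", config.doublet_model)
        res = DoubletModel(counts, model=config.doublet_model).fit(
            bootstrap=config.bootstrap, seed=config.seed
        )
        report["stages"]["doublets"] = res.to_dict()
        log.info("[doublets] single-cell frequency %.1f%%", res.single_cell_freq)

    if config.ani is not None:
        log.info("[cluster] reading %s", config.ani)
        ani, af, quality, refs = read_ani_tables(
            config.ani, config.quality, config.refs
        )
        model = StrainLineageModel(
            ani,
            af,
            quality=quality,
            references=refs,
            min_aligned_fraction=config.self_min_af,
            ref_min_aligned_fraction=config.ref_min_af,
        )
        assignment = model.fit(
            strain_ani=config.strain_ani, lineage_ani=config.lineage_ani
        )
        assignment.assignments.to_csv(
            out_dir / "cluster_assignments.tsv", sep="\t", index=False
        )
        report["stages"]["cluster"] = assignment.to_dict()
        log.info(
            "[cluster] %d strains, %d lineages, %d novel",
            assignment.n_strains,
            assignment.n_lineages,
            assignment.n_novel,
        )

    write_json(report, out_dir / "report.json")
    return report
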