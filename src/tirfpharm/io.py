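"""Configuration, file I/O and end-to-end experiment orchestration.

An experiment run is: simulate TIRF fields for each treatment x batch ->
detect and measure puncta -> pooled-median area normalization ->
batch-aggregated group statistics.  Every stage writes plain-format
outputs (16-bit TIFF fields, CSV tables) plus a JSON manifest recording
the full configuration, seeds and library versions, so a run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .puncta import PipelineConfig, run_field_analysis
from .stats import analyze_endpoint, endpoint_table_to_groups
from .synthetic import FieldSpec, NoiseModel, RawField, generate_field

__all__ = ["TreatmentSpec", "RunConfig", "run_experiment",
           "load_run_config", "write_field_tiff", "read_field_tiff"]


@dataclass(frozen=True)
class TreatmentSpec:
    label: str
    n_batches: int = 3
    fields_per_batch: int = 20
    n_puncta_per_cell: int = 10


@dataclass
class RunConfig:
    """Everything needed to reproduce an end-to-end simulated experiment."""

    output_dir: str
    seed: int
    treatments: list[TreatmentSpec] = field(default_factory=lambda: [
        TreatmentSpec("vehicle", n_puncta_per_cell=5),
        TreatmentSpec("agonist", n_puncta_per_cell=15),
    ])
    control_label: str = "vehicle"
    field_template: dict = field(default_factory=dict)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        labels = [t.label for t in self.treatments]
        if self.control_label not in labels:
            raise ValueError("control_label must be one of the treatments")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw:
        raise ValueError("config must state an explicit seed")
    treatments = [TreatmentSpec(**t) for t in raw.get("treatments", [])]
    kwargs = dict(
        output_dir=raw["output_dir"],
        seed=int(raw["seed"]),
        control_label=raw.get("control_label", "vehicle"),
        field_template=raw.get("field_template", {}),
    )
    if treatments:
        kwargs["treatments"] = treatments
    if "pipeline" in raw:
        kwargs["pipeline"] = PipelineConfig(**raw["pipeline"])
    return RunConfig(**kwargs)


def write_field_tiff(path: str | Path, field_: RawField) -> None:
    tifffile.imwrite(str(path), field_.pixels, photometric="minisblack")


def read_field_tiff(path: str | Path, field_id: str = "",
                    treatment_label: str = "", batch_id: str = "") -> RawField:
    px = tifffile.imread(str(path))
    return RawField(pixels=px, field_id=field_id or Path(path).stem,
                    treatment_label=treatment_label, batch_id=batch_id)


def write_label_overlay(path: str | Path, labels: np.ndarray) -> None:
    """Save a puncta label map as a 16-bit TIFF for downstream QC review."""
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16),
                     photometric="minisblack")


def _simulate_fields(config: RunConfig) -> list[RawField]:
    fields: list[RawField] = []
    template = dict(config.field_template)
    noise = template.pop("noise_model", None)
    if isinstance(noise, dict):
        noise = NoiseModel(**noise)
    counter = 0
    for t in config.treatments:
        for b in range(t.n_batches):
            for i in range(t.fields_per_batch):
                spec_kwargs = dict(template)
                spec_kwargs["n_puncta_per_cell"] = t.n_puncta_per_cell
                spec_kwargs["seed"] = config.seed + counter
                if noise is not None:
                    spec_kwargs["noise_model"] = noise
                raw, _gt = generate_field(FieldSpec(**spec_kwargs))
                raw.field_id = f"{t.label}-b{b}-f{i}"
                raw.treatment_label = t.label
                raw.batch_id = f"{t.label}-b{b}"
                fields.append(raw)
                counter += 1
    return fields


def run_experiment(config: RunConfig, write_images: bool = False) -> dict:
    """Simulate -> detect -> quantify -> stats; returns the result bundle.

    Writes puncta/endpoint/stats CSVs and a provenance manifest to
    ``config.output_dir``.  Rerunning with an identical config reproduces
    every numeric output byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        fields = _simulate_fields(config)
        if write_images:
            img_dir = out / "fields"
            img_dir.mkdir(exist_ok=True)
            for f in fields:
                write_field_tiff(img_dir / f"{f.field_id}.tif", f)
        stage = "detect"
        puncta_table, endpoint_table = run_field_analysis(fields,
                                                          config.pipeline)
        stage = "stats"
        groups = endpoint_table_to_groups(endpoint_table,
                                          value_col="puncta_count_norm")
        anova = analyze_endpoint(groups, config.control_label,
                                 seed=config.seed)
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    puncta_table.to_csv(out / "puncta.csv", index=False)
    endpoint_table.to_csv(out / "endpoints.csv", index=False)
    stats_rows = [("anova", "treatment", anova.F,
                   f"{anova.df_between},{anova.df_within}", anova.p, "")]
    stats_rows.append(("bartlett", "treatment", anova.bartlett_stat, "",
                       anova.bartlett_p, ""))
    for label, p_adj in anova.comparisons.items():
        stats_rows.append(("dunnett", f"{label} vs {config.control_label}",
                           "", "", "", p_adj))
    stats_table = pd.DataFrame(stats_rows, columns=[
        "test", "comparison", "statistic", "df", "p", "p_adj"])
    stats_table.to_csv(out / "stats.csv", index=False)

    manifest = {
        "tirfpharm_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": _to_jsonable(config),
        "stages": ["simulate", "detect", "stats"],
        "outputs": ["puncta.csv", "endpoints.csv", "stats.csv"],
        "n_fields": len(fields),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return {"puncta": puncta_table, "endpoints": endpoint_table,
            "anova": anova, "manifest": manifest}


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
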