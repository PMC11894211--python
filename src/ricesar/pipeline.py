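"""End-to-end orchestration: simulate -> preprocess -> fit -> classify ->
SoS -> areas -> accuracy, with a reproducible manifest.

Each stage reads and writes the standard artifacts, so stages are also
runnable one at a time (see :mod:`ricesar.cli`).  A run is fully determined
by its configuration and seed; the manifest records both together with
package versions, per-rule rejection counts and stage timings.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .areas import district_area_table, sos_area_table
from .io import (
    read_ground_truth,
    read_raster,
    read_stack,
    write_ground_truth,
    write_raster,
    write_stack,
)
from .phenology import SeasonBins, SoSMap, bin_sos_areas
from .radiometry import interpolate_anomalies, temporal_speckle_filter
from .rules import classify_stack
from .scene import SceneConfig, add_atmospheric_anomalies, build_scene
from .signatures import (
    RuleParameters,
    TrainingSignatureSet,
    extract_field_signatures,
    extract_rule_parameters,
)
from .stack import CLASS_CODES, SigmaStack
from .validation import accuracy_report, confusion_matrix, split_ground_truth

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report", "sample_ground_truth"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    anomaly_rate: float = 0.05
    anomaly_magnitude_db: float = 4.0
    filter_window_px: int = 5
    # After linear-domain spatial filtering, single-date anomalies are
    # largely absorbed, while a rice flooding trough remains a legitimate
    # ~3-4 dB single-acquisition excursion; the pipeline threshold sits
    # above it so interpolation only guards against extreme residuals.
    spike_threshold_db: float = 6.0
    margin_db: float = 0.5
    training_field_px: int = 3
    n_ground_truth: int = 300
    train_fraction: float = 0.6
    min_valid_acquisitions: int = 10
    bins: SeasonBins | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        scene = d["scene"]
        for key in ("start_date", "sos_start", "sos_end"):
            scene[key] = scene[key].isoformat()
        scene["rice_priors"] = dataclasses.asdict(self.scene.rice_priors)
        scene["nonrice_priors"] = dataclasses.asdict(self.scene.nonrice_priors)
        if self.bins is not None:
            d["bins"] = {
                k: [v[0].isoformat(), v[1].isoformat()]
                for k, v in (("early", self.bins.early), ("major", self.bins.major),
                             ("late", self.bins.late))
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = dict(d.get("scene", {}))
        for key in ("start_date", "sos_start", "sos_end"):
            if key in scene and isinstance(scene[key], str):
                scene[key] = dt.date.fromisoformat(scene[key])
        for key in ("grid_shape", "pixel_spacing_m"):
            if key in scene:
                scene[key] = tuple(scene[key])
        scene.pop("rice_priors", None)
        scene.pop("nonrice_priors", None)
        d["scene"] = SceneConfig(**scene)
        if d.get("bins"):
            b = {
                k: (dt.date.fromisoformat(v[0]), dt.date.fromisoformat(v[1]))
                for k, v in d["bins"].items()
            }
            d["bins"] = SeasonBins(**b)
        else:
            d.pop("bins", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def sample_ground_truth(
    truth,
    n_points: int,
    seed: int | np.random.Generator | None = None,
    interior_margin_px: int = 2,
) -> pd.DataFrame:
    """Random rice/non-rice survey points at pixel centres of a scene.

    Points are drawn from land-cover patch interiors (each class mask eroded
    by ``interior_margin_px``): handheld-GPS survey points are taken
    mid-field, not on 10 m parcel boundaries.  A rice monitoring field has a
    single transplanting date, so rice points are additionally interior to
    their SoS-homogeneous region.  The margin degrades automatically when a
    scene is too fragmented to supply enough interior pixels.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    h, w = truth.class_raster.shape
    if n_points > h * w:
        raise ValueError("more ground-truth points than pixels")
    rice_code = CLASS_CODES["rice"]
    for margin in range(interior_margin_px, -1, -1):
        pool = np.zeros((h, w), dtype=bool)
        for code in np.unique(truth.class_raster):
            if code == rice_code:
                for sos_value in np.unique(truth.sos_raster[truth.class_raster == code]):
                    mask = (truth.class_raster == code) & (truth.sos_raster == sos_value)
                    if margin:
                        mask = ndimage.binary_erosion(mask, iterations=margin)
                    pool |= mask
            else:
                mask = truth.class_raster == code
                if margin:
                    mask = ndimage.binary_erosion(mask, iterations=margin)
                pool |= mask
        if int(pool.sum()) >= n_points:
            break
    flat_pool = np.nonzero(pool.ravel())[0]
    flat = rng.choice(flat_pool, size=n_points, replace=False)
    rows, cols = np.divmod(flat, w)
    label = np.where(
        truth.class_raster[rows, cols] == CLASS_CODES["rice"], "rice", "nonrice"
    )
    return pd.DataFrame(
        {"x": cols + 0.5, "y": rows + 0.5, "label": label}
    )


def _default_bins(calendar) -> SeasonBins:
    """Thirds of the acquisition calendar as early/major/late windows."""
    t = len(calendar)
    i1, i2 = max(1, t // 3), max(2, 2 * t // 3)
    return SeasonBins(
        early=(calendar.dates[0], calendar.dates[i1 - 1]),
        major=(calendar.dates[i1], calendar.dates[i2 - 1]),
        late=(calendar.dates[i2], calendar.dates[-1]),
    )


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and return the run manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("scene", "anomalies", "points", "split"),
            np.random.SeedSequence(config.seed).spawn(4),
        )
    }
    manifest: dict = {
        "package": "ricesar",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "timings_s": {},
        "artifacts": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 3)

        return _Timer()

    def emit(key: str, path: Path):
        manifest["artifacts"][key] = str(path)

    with stage("simulate"):
        stack, truth = build_scene(config.scene, seeds["scene"])
        stack, anomaly_mask = add_atmospheric_anomalies(
            stack, config.anomaly_rate, config.anomaly_magnitude_db, seeds["anomalies"]
        )
        emit("stack", write_stack(stack, outdir / "stack.tif"))
        emit("truth_class", write_raster(truth.class_raster, outdir / "truth_class.tif"))
        emit("truth_sos", write_raster(truth.sos_raster, outdir / "truth_sos.tif"))
        emit("districts", write_raster(truth.district_raster, outdir / "districts.tif"))

    with stage("ground_truth"):
        points = sample_ground_truth(truth, config.n_ground_truth, seeds["points"])
        train, validate = split_ground_truth(points, config.train_fraction, seeds["split"])
        gt = pd.concat([train, validate]).sort_index()
        emit("ground_truth", write_ground_truth(gt, outdir / "ground_truth.csv"))

    with stage("preprocess"):
        filtered = temporal_speckle_filter(stack, config.filter_window_px)
        clean = interpolate_anomalies(filtered, config.spike_threshold_db)
        emit("stack_preprocessed", write_stack(clean, outdir / "stack_preprocessed.tif"))

    with stage("fit_params"):
        rice_train = train[train["label"] == "rice"]
        if len(rice_train) < 3:
            raise ValueError("fewer than 3 rice training points in the survey")
        training = extract_field_signatures(
            clean, rice_train, config.training_field_px
        )
        params = extract_rule_parameters(training, config.margin_db)
        params.to_yaml(outdir / "rule_parameters.yaml")
        emit("rule_parameters", outdir / "rule_parameters.yaml")

    with stage("classify"):
        rice_map = classify_stack(clean, params, config.min_valid_acquisitions)
        manifest["fail_counts"] = rice_map.fail_counts
        emit("rice_map", write_raster(rice_map.rice, outdir / "rice_map.tif"))

    with stage("sos"):
        sos_map = SoSMap.from_rice_map(rice_map)
        emit("sos_map", write_raster(sos_map.sos_index, outdir / "sos_map.tif"))

    with stage("areas"):
        district_table = district_area_table(rice_map, truth.district_raster)
        district_table.to_csv(outdir / "area_by_district.csv")
        emit("area_by_district", outdir / "area_by_district.csv")
        sos_table = sos_area_table(sos_map, truth.district_raster)
        sos_table.to_csv(outdir / "sos_area_table.csv")
        emit("sos_area_table", outdir / "sos_area_table.csv")
        bins = config.bins or _default_bins(clean.calendar)
        per_date = {
            d: float(sos_table.loc["Total", d.isoformat()])
            for d in clean.calendar.dates
        }
        binned = bin_sos_areas(per_date, bins)
        pd.Series(binned, name="area_ha").rename_axis("season_bin").to_csv(
            outdir / "sos_bins.csv"
        )
        emit("sos_bins", outdir / "sos_bins.csv")

    with stage("accuracy"):
        cm = confusion_matrix(rice_map.rice, validate)
        cm.to_csv(outdir / "confusion_matrix.csv")
        emit("confusion_matrix", outdir / "confusion_matrix.csv")
        report = accuracy_report(cm)
        acc = pd.DataFrame(
            {
                "metric": ["n_points", "overall_accuracy_pct", "kappa"],
                "value": [report["n_points"], report["overall_accuracy_pct"], report["kappa"]],
            }
        )
        acc.to_csv(outdir / "accuracy.csv", index=False)
        emit("accuracy", outdir / "accuracy.csv")
        manifest["accuracy"] = {
            "n_points": report["n_points"],
            "overall_accuracy_pct": report["overall_accuracy_pct"],
            "kappa": report["kappa"],
        }

    manifest["n_anomalies"] = int(anomaly_mask.sum())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def make_report(outdir: str | Path) -> Path:
    """Assemble the human-readable run summary from the written artifacts."""
    outdir = Path(outdir)
    required = ["area_by_district.csv", "sos_area_table.csv", "sos_bins.csv", "manifest.json"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing artifacts for report: {missing}")
    manifest = json.loads((outdir / "manifest.json").read_text())
    district = pd.read_csv(outdir / "area_by_district.csv", index_col=0)
    sos_table = pd.read_csv(outdir / "sos_area_table.csv", index_col=0)
    bins = pd.read_csv(outdir / "sos_bins.csv", index_col=0)

    lines = [
        "ricesar run summary",
        "===================",
        f"seed: {manifest['seed']}   version: {manifest['version']}",
        "",
        "Rice area by district (ha, rounded):",
        district.round(0).astype(int).to_string(),
        "",
        "Rice area by start-of-season date (ha, rounded):",
        sos_table.loc[["Total"]].round(0).astype(int).to_string(),
        "",
        "Season bins (ha):",
        bins.round(0).astype(int).to_string(),
        "",
    ]
    total_rice = float(district.loc["Total", "area_ha"])
    if total_rice == 0:
        lines.append("No rice detected; accuracy assessment skipped.")
    elif (outdir / "accuracy.csv").exists():
        acc = pd.read_csv(outdir / "accuracy.csv")
        lines += ["Accuracy assessment:", acc.to_string(index=False)]
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
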