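"""End-to-end orchestration: scenes -> features -> clean -> augment -> split
-> fit -> report, driven by a single config and explicit seeds.

Every stage persists its output under the run directory and records its
row counts and file hashes in ``manifest.json``; re-running the same
config reproduces every deterministic stage byte for byte.  Stages are
also callable individually (the CLI exposes them one by one).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    Dataset,
    augment_mvn,
    dataset_from_features,
    density_filter,
    read_measurements,
    split_train_test,
)
from .evaluation import (
    EvalConfig,
    abs_pct_error_stats,
    bland_altman,
    evaluate,
    levene_residual_variance,
    paired_t_abs_errors,
)
from .exceptions import CalibrationError, GeometryError, ParameterError
from .geometry import FEATURE_COLUMNS, extract_features
from .masks import read_mask_image
from .models import DEFAULT_MODEL_IDS, fit_and_compare, fit_model, save_model
from .synth import make_fruit_population, read_manifest, render_views, write_scenes

log = logging.getLogger("mangovol")

__all__ = ["RunConfig", "run_pipeline", "extract_features_directory"]


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 1
    input_mode: str = "synthetic"  # or "mask_directory"
    # synthetic-scene population
    n_fruits: int = 450
    volume_mean: float = 51.52
    volume_sd: float = 10.61
    aspect_jitter: float = 0.1
    calyx_scale: float = 1.0
    mm_per_px: float = 0.5
    marker_side_mm: float = 30.0
    # mask-directory inputs
    mask_dir: str | None = None
    measurements_csv: str | None = None
    # processing
    exclude_calyx: bool = True
    density_threshold: float = 1.00
    n_synth: int = 450
    clamp_min: float = 0.01
    train_fraction: float = 0.8
    model_ids: tuple = tuple(DEFAULT_MODEL_IDS)
    reference_model: str = "N"
    epsilon: float = 1e-6
    loa_multiplier: float = 1.96

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "mask_directory"):
            raise ParameterError("input_mode must be 'synthetic' or 'mask_directory'")
        self.model_ids = tuple(self.model_ids)

    # deterministic per-stage seeds, all below 2**31
    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["model_ids"] = list(self.model_ids)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    @property
    def eval_config(self) -> EvalConfig:
        return EvalConfig(epsilon=self.epsilon, loa_multiplier=self.loa_multiplier)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_features_directory(
    manifest: pd.DataFrame,
    mask_dir,
    marker_area_mm2: float = 900.0,
    exclude_calyx: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table from a directory of per-class PNG masks.

    ``manifest`` needs columns id and view (two rows per fruit); masks are
    read from ``{id}_{view}_{class}.png``.  Returns (features, skipped):
    skipped rows carry a reason code (calibration_failed,
    empty_fruit_mask) instead of aborting the run.
    """
    mask_dir = Path(mask_dir)
    rows, skipped = [], []
    for fruit_id, group in manifest.groupby("id", sort=False):
        views = {}
        try:
            for view in ("side", "bottom"):
                views[view] = tuple(
                    read_mask_image(mask_dir / f"{fruit_id}_{view}_{cls}.png")
                    for cls in ("fruit", "calyx", "marker")
                )
            fv = extract_features(
                views["side"], views["bottom"], marker_area_mm2, exclude_calyx
            )
        except CalibrationError as exc:
            skipped.append({"id": fruit_id, "reason": "calibration_failed", "detail": str(exc)})
            continue
        except (GeometryError, FileNotFoundError) as exc:
            skipped.append({"id": fruit_id, "reason": "empty_fruit_mask", "detail": str(exc)})
            continue
        rows.append({"id": fruit_id, **fv.as_row()})
    features = pd.DataFrame(rows, columns=["id", *FEATURE_COLUMNS])
    return features, pd.DataFrame(skipped, columns=["id", "reason", "detail"])


def _stage_scenes(config: RunConfig, outdir: Path) -> pd.DataFrame:
    fruits = make_fruit_population(
        config.n_fruits,
        config.volume_mean,
        config.volume_sd,
        config.aspect_jitter,
        config.calyx_scale,
        seed=config.stage_seed("population"),
    )
    rng = np.random.default_rng(config.stage_seed("placement"))
    scenes = []
    for fruit in fruits:
        side, bottom = render_views(fruit, config.mm_per_px, config.marker_side_mm, rng)
        scenes.extend([side, bottom])
    return write_scenes(scenes, outdir / "scenes")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in order and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    counts: dict[str, int] = {}

    # 1. scenes --------------------------------------------------------
    if config.input_mode == "synthetic":
        log.info("stage simulate: %d fruits at %.3g mm/px", config.n_fruits, config.mm_per_px)
        manifest = _stage_scenes(config, outdir)
        mask_dir = outdir / "scenes"
        measurements = (
            manifest.drop_duplicates("id")[["id", "mass", "true_volume"]]
            .rename(columns={"mass": "mass_g", "true_volume": "volume_cm3"})
        )
    else:
        if not config.mask_dir or not config.measurements_csv:
            raise ParameterError("mask_directory mode needs mask_dir and measurements_csv")
        mask_dir = Path(config.mask_dir)
        manifest = read_manifest(mask_dir)
        measurements = read_measurements(config.measurements_csv)
    counts["scenes"] = int(len(manifest))

    # 2. features ------------------------------------------------------
    features, skipped = extract_features_directory(
        manifest, mask_dir, exclude_calyx=config.exclude_calyx
    )
    features.to_csv(outdir / "features.csv", index=False)
    skipped.to_csv(outdir / "features_skipped.csv", index=False)
    counts["features"] = len(features)
    counts["features_skipped"] = len(skipped)

    # 3. assemble + density filter ------------------------------------
    dataset = dataset_from_features(features, measurements)
    kept, dropped = density_filter(dataset, config.density_threshold)
    kept.to_csv(outdir / "dataset_clean.csv")
    dropped.records.to_csv(outdir / "dataset_dropped.csv", index=False)
    counts["clean_kept"] = len(kept)
    counts["clean_dropped"] = len(dropped)
    if counts["clean_kept"] + counts["clean_dropped"] != len(dataset):
        raise RuntimeError("density filter lost records")  # conservation ledger

    # 4. augment -------------------------------------------------------
    augmented = augment_mvn(
        kept, config.n_synth, seed=config.stage_seed("augment"), clamp_min=config.clamp_min
    )
    augmented.to_csv(outdir / "dataset_augmented.csv")
    counts["augmented"] = len(augmented)

    # 5. split ---------------------------------------------------------
    train, test = split_train_test(
        augmented, config.train_fraction, seed=config.stage_seed("split")
    )
    train.to_csv(outdir / "train.csv")
    test.to_csv(outdir / "test.csv")
    counts["train"] = len(train)
    counts["test"] = len(test)

    # 6. fit -----------------------------------------------------------
    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    fitted = {}
    for mid in config.model_ids:
        model = fit_model(mid, train)
        fitted[mid] = model
        if model.coef_ is not None:
            save_model(model, model_dir / f"model_{mid}.json")

    # 7. report --------------------------------------------------------
    comparison = fit_and_compare(config.model_ids, train, test, config.eval_config)
    comparison.to_csv(outdir / "model_comparison.csv", index=False)

    y_test = test.records["v_true"].to_numpy(float)
    summary_rows = []
    diag: dict[str, dict] = {}
    ref_id = config.reference_model
    ref_pred = fitted[ref_id].predict(test.records) if ref_id in fitted else None
    for mid, model in fitted.items():
        pred = model.predict(test.records)
        stats7 = abs_pct_error_stats(y_test, pred, config.eval_config)
        summary_rows.append({"Model": mid, **stats7._asdict()})
        report = evaluate(y_test, pred, config.eval_config)
        ba = bland_altman(y_test, pred, config.eval_config)
        entry = {
            "r2": report.r2,
            "mape_pct": report.mape,
            "rmse_cm3": report.rmse,
            "bias_cm3": report.bias,
            "bland_altman": ba._asdict(),
            "n_negative_pred": report.n_negative_pred,
        }
        if ref_pred is not None and mid != ref_id:
            t, p = paired_t_abs_errors(y_test - pred, y_test - ref_pred)
            w, lp = levene_residual_variance(y_test - pred, y_test - ref_pred)
            entry["paired_t_vs_reference"] = {"t": t, "p": p}
            entry["levene_vs_reference"] = {"W": w, "p": lp}
        diag[mid] = entry
    pd.DataFrame(summary_rows).to_csv(outdir / "abs_pct_error_stats.csv", index=False)
    (outdir / "diagnostics.json").write_text(json.dumps(diag, indent=2, sort_keys=True))

    manifest_payload = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: config.stage_seed(s) for s in ("population", "placement", "augment", "split")
        },
        "counts": counts,
        "hashes": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest_payload, indent=2, sort_keys=True))
    return manifest_payload
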