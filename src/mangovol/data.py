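"""Build, clean, augment and split the modeling table.

A :class:`Dataset` wraps a pandas DataFrame with one row per fruit:
the nine geometric features, the fresh mass (g), the water-displacement
reference volume ``v_true`` (cm^3), and an ``origin`` flag (real vs
synthetic).  Density is always recomputed from mass and volume, never
stored, so it cannot go stale.

Cleaning discards physically impossible samples (density below
1.00 g/cm^3 indicates a measurement error: the pericarp is denser than
water).  Augmentation draws synthetic feature/label rows from a
multivariate normal fitted to the cleaned table, preserving the joint
covariance structure of the descriptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .geometry import FEATURE_COLUMNS, extract_features

RECORD_COLUMNS = ["id", *FEATURE_COLUMNS, "mass_g", "v_true", "origin"]

# the augmentation vector: core geometric features plus the training label,
# drawn jointly so synthetic labels co-vary with synthetic features
AUGMENT_COLUMNS = ["A_s", "A_b", "h", "w", "d1", "d2", "V_e", "v_true"]

__all__ = [
    "Dataset",
    "RECORD_COLUMNS",
    "AUGMENT_COLUMNS",
    "dataset_from_scenes",
    "dataset_from_features",
    "read_measurements",
    "density_filter",
    "augment_mvn",
    "split_train_test",
    "descriptive_stats",
]


@dataclass
class Dataset:
    """The modeling table plus provenance and a log of every seed used."""

    records: pd.DataFrame
    provenance: str = ""
    seed_log: list = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ParameterError(f"dataset missing columns: {missing}")
        if self.records["id"].duplicated().any():
            raise ParameterError("dataset ids must be unique")
        if (self.records["v_true"] <= 0).any():
            raise ParameterError("v_true must be positive for every record")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def density(self) -> pd.Series:
        """g/cm^3, recomputed on access (NaN for synthetic rows without mass)."""
        return self.records["mass_g"] / self.records["v_true"]

    def copy(self) -> "Dataset":
        return Dataset(self.records.copy(), self.provenance, list(self.seed_log))

    def to_csv(self, path) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        sidecar = path.with_suffix(".seeds.json")
        sidecar.write_text(
            json.dumps({"provenance": self.provenance, "seed_log": self.seed_log}, indent=2)
        )

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        path = Path(path)
        records = pd.read_csv(path)
        provenance, seed_log = "", []
        sidecar = path.with_suffix(".seeds.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            provenance = meta.get("provenance", "")
            seed_log = [tuple(e) for e in meta.get("seed_log", [])]
        return cls(records, provenance, seed_log)


def dataset_from_scenes(scene_pairs, exclude_calyx: bool = True,
                        marker_area_mm2: float = 900.0) -> Dataset:
    """Extract features from rendered (side, bottom) scene pairs.

    Ground-truth volume and mass come from the generating fruit specs, so
    the result plays the role of the measured table in synthetic studies.
    """
    rows = []
    for side, bottom in scene_pairs:
        fv = extract_features(side, bottom, marker_area_mm2, exclude_calyx)
        rows.append(
            {
                "id": side.fruit.id,
                **fv.as_row(),
                "mass_g": side.fruit.mass,
                "v_true": side.true_volume,
                "origin": "real",
            }
        )
    return Dataset(pd.DataFrame(rows, columns=RECORD_COLUMNS), provenance="synthetic scenes")


def dataset_from_features(features: pd.DataFrame, measurements: pd.DataFrame) -> Dataset:
    """Join a feature table (id + nine features) with a measurement table
    (id, mass_g, volume_cm3) into a modeling dataset."""
    merged = features.merge(measurements, on="id", how="inner")
    merged = merged.rename(columns={"volume_cm3": "v_true"})
    merged["origin"] = "real"
    return Dataset(merged[RECORD_COLUMNS], provenance="features + measurements")


def read_measurements(path) -> pd.DataFrame:
    """Measurement CSV with columns id, mass_g, volume_cm3 (water displacement)."""
    df = pd.read_csv(path)
    missing = {"id", "mass_g", "volume_cm3"} - set(df.columns)
    if missing:
        raise ParameterError(f"measurement table missing columns: {sorted(missing)}")
    return df


def density_filter(data: Dataset, threshold: float = 1.00) -> tuple[Dataset, Dataset]:
    """Partition into (kept, dropped) by density.

    Records with density strictly below ``threshold`` are discarded as
    measurement errors; equality is kept.  Rows without a mass (synthetic)
    have undefined density and are kept.  Both partitions are returned for
    audit; together they are exactly the input.
    """
    density = data.density
    drop = density < threshold  # NaN compares False -> kept
    kept = Dataset(data.records[~drop].copy(), data.provenance, list(data.seed_log))
    dropped = Dataset(
        data.records[drop].copy(),
        data.provenance + " [dropped by density filter]",
        list(data.seed_log),
    )
    return kept, dropped


def augment_mvn(
    data: Dataset, n_synth: int, seed: int, clamp_min: float = 0.01
) -> Dataset:
    """Append multivariate-normal synthetic rows to the dataset.

    The mean vector and covariance matrix of ``AUGMENT_COLUMNS`` (features
    plus the true volume) are estimated from the input records; ``n_synth``
    joint draws are taken, every component is clamped at ``clamp_min`` to
    stay physically plausible, and the power-law features are recomputed
    from the clamped areas.  Synthetic rows carry ``origin='synthetic'``
    and no mass.  Original rows come first in the output.

    A singular covariance gets a small diagonal ridge (1e-8 x mean
    diagonal), noted in the seed log, rather than aborting.
    """
    if n_synth < 0:
        raise ParameterError("n_synth must be >= 0")
    if n_synth == 0:
        return data.copy()
    if len(data) < 2:
        raise ParameterError("need >= 2 records to estimate a covariance")

    values = data.records[AUGMENT_COLUMNS].to_numpy(float)
    mean = values.mean(axis=0)
    cov = np.cov(values, rowvar=False)
    log = list(data.seed_log)
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        ridge = 1e-8 * float(np.mean(np.diag(cov)))
        cov = cov + ridge * np.eye(cov.shape[0])
        log.append(("augment_mvn.ridge", ridge))

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_synth, method="svd")
    draws = np.maximum(draws, clamp_min)

    synth = pd.DataFrame(draws, columns=AUGMENT_COLUMNS)
    synth["A_s15"] = synth["A_s"] ** 1.5
    synth["A_b15"] = synth["A_b"] ** 1.5
    synth["id"] = [f"synth{i:05d}" for i in range(n_synth)]
    synth["mass_g"] = np.nan
    synth["origin"] = "synthetic"
    combined = pd.concat(
        [data.records, synth[RECORD_COLUMNS]], ignore_index=True
    )
    log.append(("augment_mvn", seed))
    return Dataset(combined, data.provenance + " + MVN augmentation", log)


def split_train_test(
    data: Dataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Uniformly random disjoint partition; |train| = round(fraction * N)."""
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must be in (0, 1)")
    n = len(data)
    if n < 2:
        raise ParameterError("need >= 2 records to split")
    n_train = int(round(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    log = list(data.seed_log) + [("split_train_test", seed)]
    train = Dataset(data.records.iloc[np.sort(perm[:n_train])].copy(),
                    data.provenance + " [train]", log)
    test = Dataset(data.records.iloc[np.sort(perm[n_train:])].copy(),
                   data.provenance + " [test]", log)
    return train, test


def descriptive_stats(data: Dataset, columns) -> pd.DataFrame:
    """Mean, sample SD, min, quartiles (linear interpolation) and max per column."""
    if len(data) < 1:
        raise ParameterError("need >= 1 record")
    unknown = [c for c in columns if c not in data.records.columns]
    if unknown:
        raise ParameterError(f"unknown columns: {unknown}")
    out = {}
    for c in columns:
        v = data.records[c].to_numpy(float)
        out[c] = {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)),
            "q1": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "q3": float(np.quantile(v, 0.75)),
            "max": float(np.max(v)),
        }
    return pd.DataFrame(out)
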