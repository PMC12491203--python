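"""On-disk formats: joint-angle trials, cohort metadata, feature matrices.

All files are comma-separated UTF-8 text with a mandatory header row and a
decimal point.  A *trial* file holds one subject's sampled joint angles
(columns ``time_s, hip_deg, knee_deg, ankle_deg``; remappable through a
schema).  The *cohort metadata* table has one row per subject with group
label, covariates and optional spatiotemporal gait parameters (empty cells
encode missing values; downstream median imputation handles them).

Angle sign convention: flexion positive; for the ankle, dorsiflexion
positive and plantarflexion negative.  Gait-event detection relies on this
convention (toe-off is the plantarflexion *minimum*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("gaitfusion.io")

GROUPS = ("Healthy", "KOA", "TKA")
SIDE_CATEGORIES = ("unilateral_left", "unilateral_right", "bilateral", "none")
JOINTS = ("hip", "knee", "ankle")
SPATIOTEMPORAL_KEYS = (
    "speed",
    "stride_length",
    "stride_width",
    "step_length_left",
    "step_length_right",
)
DEFAULT_TRIAL_SCHEMA = {"hip": "hip_deg", "knee": "knee_deg", "ankle": "ankle_deg"}

META_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "bmi",
    "side_category",
) + SPATIOTEMPORAL_KEYS


class SchemaError(ValueError):
    """A required column is missing or a label is not recognized."""


@dataclass
class JointAngleSeries:
    """One joint's sampled flexion-angle trace for one trial, degrees."""

    joint: str
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.ndim != 1:
            raise ValueError("angle trace must be one-dimensional")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError(f"{self.joint} trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass
class TrialRecording:
    """Hip/knee/ankle angle traces of one walking trial, equal length."""

    subject_id: str
    side: str
    sampling_rate: float
    traces: dict[str, JointAngleSeries]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = set(JOINTS) - set(self.traces)
        if missing:
            raise SchemaError(f"missing joint traces: {sorted(missing)}")
        lengths = {j: len(t) for j, t in self.traces.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"trace lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(self.traces["hip"])


@dataclass
class SubjectMeta:
    """Group label, covariates and spatiotemporal parameters of a subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    bmi: float
    side_category: str = "none"
    spatiotemporal: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"unknown group {self.group!r} for {self.subject_id}; "
                f"expected one of {GROUPS}"
            )
        if self.side_category not in SIDE_CATEGORIES:
            raise SchemaError(
                f"unknown side_category {self.side_category!r} "
                f"for {self.subject_id}"
            )
        for name, value in (("age", self.age), ("bmi", self.bmi)):
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite for {self.subject_id}")
        for key, value in self.spatiotemporal.items():
            if key not in SPATIOTEMPORAL_KEYS:
                raise SchemaError(f"unknown spatiotemporal key {key!r}")
            if value is not None and not np.isfinite(value):
                raise ValueError(f"{key} must be finite when present")


def read_trial(
    path: str | Path,
    schema: dict[str, str] | None = None,
    subject_id: str | None = None,
    side: str = "left",
    sampling_rate: float = 100.0,
) -> TrialRecording:
    """Read one trial CSV into a validated :class:`TrialRecording`.

    ``schema`` maps joint name -> column name; row order is time order.
    """
    path = Path(path)
    schema = dict(DEFAULT_TRIAL_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, skip_blank_lines=True, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    traces: dict[str, JointAngleSeries] = {}
    for joint in JOINTS:
        col = schema.get(joint)
        if col is None or col not in df.columns:
            raise SchemaError(f"trial file {path.name} lacks column {col!r} for joint {joint!r}")
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric cell in column {col!r} at row {int(bad[0])}")
        if values.isna().any():
            raise ValueError(f"missing angle value in column {col!r}")
        traces[joint] = JointAngleSeries(joint, values.to_numpy())
    if subject_id is None:
        subject_id = path.stem
    return TrialRecording(subject_id, side, sampling_rate, traces)


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial back to the CSV interchange format (full precision)."""
    n = trial.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / trial.sampling_rate,
            "hip_deg": trial.traces["hip"].angles_deg,
            "knee_deg": trial.traces["knee"].angles_deg,
            "ankle_deg": trial.traces["ankle"].angles_deg,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _meta_from_row(row: pd.Series) -> SubjectMeta:
    spatio = {}
    for key in SPATIOTEMPORAL_KEYS:
        if key in row.index and pd.notna(row[key]):
            spatio[key] = float(row[key])
    return SubjectMeta(
        subject_id=str(row["subject_id"]).strip(),
        group=str(row["group"]).strip(),
        age=float(row["age"]),
        sex=str(row["sex"]).strip(),
        bmi=float(row["bmi"]),
        side_category=str(row["side_category"]).strip() if pd.notna(row.get("side_category")) else "none",
        spatiotemporal=spatio,
    )


def read_cohort(
    meta_path: str | Path,
    trials_dir: str | Path,
    schema: dict[str, str] | None = None,
    sampling_rate: float = 100.0,
) -> list[tuple[SubjectMeta, TrialRecording]]:
    """Join the metadata table with per-subject trial files.

    Each subject must have a trial file ``<trials_dir>/<subject_id>.csv``.
    Subjects without a trial file are reported collectively in the raised
    error, never silently dropped.  Row order of the metadata table does
    not matter: the cohort is sorted by subject_id.
    """
    meta_path, trials_dir = Path(meta_path), Path(trials_dir)
    meta = pd.read_csv(meta_path, skip_blank_lines=True, float_precision="round_trip")
    meta.columns = [c.strip() for c in meta.columns]
    ids = meta["subject_id"].astype(str).str.strip()
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate subject_id in metadata: {sorted(set(dup))}")
    cohort: list[tuple[SubjectMeta, TrialRecording]] = []
    missing: list[str] = []
    for _, row in meta.iterrows():
        sm = _meta_from_row(row)
        trial_path = trials_dir / f"{sm.subject_id}.csv"
        if not trial_path.exists():
            missing.append(sm.subject_id)
            continue
        trial = read_trial(trial_path, schema=schema, subject_id=sm.subject_id,
                           sampling_rate=sampling_rate)
        cohort.append((sm, trial))
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} subject(s) have no trial file in {trials_dir}: "
            f"{sorted(missing)}"
        )
    cohort.sort(key=lambda pair: pair[0].subject_id)
    return cohort


def write_cohort_meta(metas: list[SubjectMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        row = {
            "subject_id": m.subject_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "bmi": m.bmi,
            "side_category": m.side_category,
        }
        for key in SPATIOTEMPORAL_KEYS:
            row[key] = m.spatiotemporal.get(key, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_feature_matrix(matrix: "FeatureMatrix", path: str | Path) -> None:
    """Write a feature matrix: one row per subject, deterministic columns.

    Layout: ``subject_id``, feature columns in the matrix's canonical
    order, then ``group`` and covariate columns.  A category-tag comment
    line is not written; tags are reconstructed from feature names.
    """
    from .matrix import FeatureMatrix  # local import avoids a cycle

    assert isinstance(matrix, FeatureMatrix)
    df = matrix.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path: str | Path) -> "FeatureMatrix":
    from .matrix import FeatureMatrix

    df = pd.read_csv(path, skip_blank_lines=True, float_precision="round_trip")
    return FeatureMatrix.from_frame(df)
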