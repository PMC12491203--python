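"""Subjects × features container shared by the stats and ML layers.

Feature columns carry a category tag — ``cyclogram`` (10 morphological
features of the hip–knee angle-angle diagram), ``entropy`` (sample entropy
of hip/knee/ankle angle sequences) or ``spatiotemporal`` (classical gait
parameters).  The fused feature set used for classification is the union
of the cyclogram and entropy categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CYCLOGRAM_FEATURES = (
    "hip_rom",
    "knee_rom",
    "hip_com",
    "knee_com",
    "perimeter_stance",
    "perimeter_swing",
    "perimeter_total",
    "area_stance",
    "area_swing",
    "area_total",
)
ENTROPY_FEATURES = ("se_hip", "se_knee", "se_ankle")
SPATIOTEMPORAL_FEATURES = (
    "speed",
    "stride_length",
    "stride_width",
    "step_length_left",
    "step_length_right",
)
ALL_FEATURES = CYCLOGRAM_FEATURES + ENTROPY_FEATURES + SPATIOTEMPORAL_FEATURES
FEATURE_CATEGORY = {
    **{f: "cyclogram" for f in CYCLOGRAM_FEATURES},
    **{f: "entropy" for f in ENTROPY_FEATURES},
    **{f: "spatiotemporal" for f in SPATIOTEMPORAL_FEATURES},
}
COVARIATE_COLUMNS = ("age", "sex", "bmi", "side_category")


@dataclass
class FeatureMatrix:
    """Validated subjects × features table with group labels and covariates.

    ``data`` is indexed by ``subject_id`` and contains the feature columns
    (in canonical order), ``group``, and the covariates.  Missing
    spatiotemporal values are allowed (NaN) and handled downstream by
    fold-wise median imputation.
    """

    data: pd.DataFrame
    categories: dict[str, str] = field(default_factory=lambda: dict(FEATURE_CATEGORY))

    def __post_init__(self) -> None:
        if self.data.index.name != "subject_id":
            raise ValueError("FeatureMatrix data must be indexed by subject_id")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
        if "group" not in self.data.columns:
            raise ValueError("FeatureMatrix must carry a 'group' column")
        untagged = [
            c for c in self.feature_names if c not in self.categories
        ]
        if untagged:
            raise ValueError(f"feature columns without a category tag: {untagged}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c in FEATURE_CATEGORY]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def features_of(self, category: str) -> list[str]:
        return [f for f in self.feature_names if self.categories[f] == category]

    def view(self, features: list[str]) -> pd.DataFrame:
        return self.data[features]

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f for f in ALL_FEATURES if f in self.data.columns]
            + ["group"]
            + [c for c in COVARIATE_COLUMNS if c in self.data.columns]
        )
        return self.data[cols].reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        df = df.set_index("subject_id")
        numeric = [c for c in df.columns
                   if c in FEATURE_CATEGORY or c in ("age", "bmi")]
        df[numeric] = df[numeric].astype(float)
        return cls(df)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "FeatureMatrix":
        df = pd.DataFrame(rows).set_index("subject_id")
        order = (
            [f for f in ALL_FEATURES if f in df.columns]
            + ["group"]
            + [c for c in COVARIATE_COLUMNS if c in df.columns]
        )
        return cls(df[order])

    def __len__(self) -> int:
        return len(self.data)
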