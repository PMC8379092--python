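"""Cohort schema: feature naming, phenotype records, and table I/O.

The pipeline operates on a subjects x features table of region-wise
imaging means -- diffusion-tensor metrics (FA, MD, AD, RD) over the 48
ICBM-DTI-81 white-matter labels plus arterial-spin-labeling CBF over the
116 AAL gray-matter labels -- together with a phenotype table carrying
the diagnosis label (1 = vascular mild cognitive impairment, 0 =
cognitively normal small-vessel-disease control), demographics, and
cognitive test scores.

Feature columns are named ``modality__metric__region`` (double
underscore), e.g. ``diffusion__FA__right_anterior_corona_radiata`` or
``perfusion__CBF__Rolandic_Oper_R``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureName",
    "SubjectRecord",
    "Cohort",
    "SchemaError",
    "AlignmentError",
    "ValidationError",
    "DIFFUSION_METRICS",
    "COGNITIVE_TESTS",
    "wm_labels",
    "gm_labels",
    "build_feature_index",
    "default_feature_index",
    "load_cohort",
    "write_cohort",
]

DIFFUSION_METRICS = ("FA", "MD", "AD", "RD")
PERFUSION_METRIC = "CBF"

#: cognitive columns recognised in the phenotype table (optional as a set);
#: TMT and Stroop scores are completion/reaction times in seconds, the
#: rest are points.
COGNITIVE_TESTS = ("MoCA", "MMSE", "TMT_A", "TMT_B", "Stroop_CT", "VFT")

PHENOTYPE_BASE_COLUMNS = ("subject_id", "diagnosis", "sex", "age", "education")


class SchemaError(ValueError):
    """Malformed feature index or column naming."""


class AlignmentError(ValueError):
    """Subject sets of the feature and phenotype tables disagree."""


class ValidationError(ValueError):
    """Missing or non-numeric cells; no imputation is ever attempted."""


@dataclass(frozen=True)
class FeatureName:
    """A single atlas-wise imaging feature.

    ``metric`` determines everything else: FA/MD/AD/RD features are
    diffusion features over ICBM-DTI-81 white-matter labels; CBF
    features are perfusion features over AAL gray-matter labels.
    """

    metric: str
    region: str

    def __post_init__(self) -> None:
        if self.metric not in DIFFUSION_METRICS + (PERFUSION_METRIC,):
            raise SchemaError(f"unknown metric {self.metric!r}")
        if not self.region or "__" in self.region:
            raise SchemaError(f"bad region label {self.region!r}")

    @property
    def modality(self) -> str:
        return "perfusion" if self.metric == PERFUSION_METRIC else "diffusion"

    @property
    def atlas(self) -> str:
        return "AAL" if self.metric == PERFUSION_METRIC else "ICBM_DTI_81"

    @property
    def column(self) -> str:
        return f"{self.modality}__{self.metric}__{self.region}"

    @classmethod
    def from_column(cls, column: str) -> "FeatureName":
        parts = column.split("__")
        if len(parts) != 3:
            raise SchemaError(
                f"feature column {column!r} is not modality__metric__region"
            )
        modality, metric, region = parts
        name = cls(metric=metric, region=region)
        if name.modality != modality:
            raise SchemaError(
                f"column {column!r}: metric {metric} implies modality "
                f"{name.modality}, not {modality}"
            )
        return name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.column


@dataclass
class SubjectRecord:
    """Phenotype record for one subject.

    diagnosis: 1 = vMCI case, 0 = control. sex: 1 = male, 0 = female.
    age and education in years. cognitive_scores maps test name
    (see :data:`COGNITIVE_TESTS`) to the raw score.
    """

    subject_id: str
    diagnosis: int
    sex: int
    age: float
    education: float
    cognitive_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id}: diagnosis must be 0/1, "
                f"got {self.diagnosis!r}"
            )
        if self.sex not in (0, 1):
            raise ValidationError(
                f"subject {self.subject_id}: sex must be 0/1, got {self.sex!r}"
            )
        if self.age < 0 or self.education < 0:
            raise ValidationError(
                f"subject {self.subject_id}: age/education must be non-negative"
            )


class Cohort:
    """Aligned phenotype records and feature table.

    Internally the feature table is a :class:`pandas.DataFrame` indexed
    by subject_id with one column per :class:`FeatureName` (in index
    order); the phenotype records live in a parallel list sorted the
    same way.
    """

    def __init__(
        self, subjects: Sequence[SubjectRecord], table: pd.DataFrame
    ) -> None:
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject_id in cohort")
        if list(table.index) != ids:
            raise AlignmentError(
                "feature table rows do not match phenotype subjects"
            )
        self.feature_index: list[FeatureName] = [
            FeatureName.from_column(c) for c in table.columns
        ]
        seen = set()
        for f in self.feature_index:
            key = (f.metric, f.region)
            if key in seen:
                raise SchemaError(f"duplicate feature {f.column}")
            seen.add(key)
        if table.isna().to_numpy().any():
            raise ValidationError("feature table contains missing values")
        self.subjects = list(subjects)
        self.table = table.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    @property
    def diagnosis(self) -> np.ndarray:
        return np.array([s.diagnosis for s in self.subjects], dtype=int)

    @property
    def sex(self) -> np.ndarray:
        return np.array([s.sex for s in self.subjects], dtype=int)

    def covariates(self) -> np.ndarray:
        """Sex/age/education matrix (n x 3), sex as a 0/1 indicator."""
        return np.array(
            [[s.sex, s.age, s.education] for s in self.subjects], dtype=float
        )

    def cognitive(self, test: str) -> np.ndarray:
        out = np.empty(self.n_subjects)
        for i, s in enumerate(self.subjects):
            if test not in s.cognitive_scores:
                raise ValidationError(
                    f"subject {s.subject_id} lacks cognitive score {test}"
                )
            out[i] = s.cognitive_scores[test]
        return out

    def values(self, features: Sequence[FeatureName] | None = None) -> np.ndarray:
        if features is None:
            return self.table.to_numpy(dtype=float)
        return self.table[[f.column for f in features]].to_numpy(dtype=float)

    def restrict_features(self, modality: str) -> "Cohort":
        """Subset to one modality ('diffusion' or 'perfusion')."""
        if modality not in ("diffusion", "perfusion"):
            raise SchemaError(f"unknown modality {modality!r}")
        cols = [f.column for f in self.feature_index if f.modality == modality]
        if not cols:
            raise SchemaError(f"cohort has no {modality} features")
        return Cohort(self.subjects, self.table[cols])

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        """Subset to the given ids, rows sorted by subject_id so results
        never depend on the caller's (or a file's) row order."""
        wanted = set(subject_ids)
        subs = sorted(
            (s for s in self.subjects if s.subject_id in wanted),
            key=lambda s: s.subject_id,
        )
        if len(subs) != len(wanted):
            raise AlignmentError("subset ids not all present in cohort")
        return Cohort(subs, self.table.loc[[s.subject_id for s in subs]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and [f.column for f in self.feature_index]
            == [f.column for f in other.feature_index]
            and np.array_equal(self.table.to_numpy(), other.table.to_numpy())
            and all(
                a.diagnosis == b.diagnosis
                and a.sex == b.sex
                and a.age == b.age
                and a.education == b.education
                and a.cognitive_scores == b.cognitive_scores
                for a, b in zip(self.subjects, other.subjects)
            )
        )


# -- packaged atlas vocabularies -----------------------------------------

def _read_labels(resource: str) -> list[str]:
    text = (
        importlib.resources.files("diffperf.data").joinpath(resource).read_text()
    )
    return [line.strip() for line in text.splitlines() if line.strip()]


def wm_labels() -> list[str]:
    """The 48 ICBM-DTI-81 white-matter label names shipped with the package."""
    return _read_labels("icbm_dti81_labels.txt")


def gm_labels() -> list[str]:
    """The 116 AAL gray-matter label names shipped with the package."""
    return _read_labels("aal_labels.txt")


def build_feature_index(
    wm: Sequence[str], gm: Sequence[str]
) -> list[FeatureName]:
    """Feature index: FA, MD, AD, RD per WM label, then CBF per GM label.

    Deterministic ordering: 4*len(wm) diffusion names followed by
    len(gm) perfusion names.
    """
    for labels, what in ((wm, "WM"), (gm, "GM")):
        if len(set(labels)) != len(labels):
            raise SchemaError(f"duplicate {what} labels")
    index = [
        FeatureName(metric=m, region=r) for r in wm for m in DIFFUSION_METRICS
    ]
    index += [FeatureName(metric=PERFUSION_METRIC, region=r) for r in gm]
    return index


def default_feature_index() -> list[FeatureName]:
    """The full 308-feature index over the packaged atlas vocabularies."""
    return build_feature_index(wm_labels(), gm_labels())


# -- I/O ------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(
        path, sep=sep, dtype={"subject_id": str},
        float_precision="round_trip",
    )


def load_cohort(feature_path: str | Path, phenotype_path: str | Path) -> Cohort:
    """Load and validate a cohort from a feature table and phenotype table.

    Rows are aligned by subject_id; a subject present in only one file
    is an :class:`AlignmentError`, any missing numeric cell a
    :class:`ValidationError` (never imputed).
    """
    feat = _read_table(feature_path)
    phen = _read_table(phenotype_path)
    for df, path in ((feat, feature_path), (phen, phenotype_path)):
        if "subject_id" not in df.columns:
            raise SchemaError(f"{path}: missing subject_id column")
    missing = set(PHENOTYPE_BASE_COLUMNS) - set(phen.columns)
    if missing:
        raise SchemaError(f"{phenotype_path}: missing columns {sorted(missing)}")

    feat_ids, phen_ids = set(feat["subject_id"]), set(phen["subject_id"])
    if feat_ids != phen_ids:
        only = feat_ids ^ phen_ids
        raise AlignmentError(
            f"subjects present in only one file: {sorted(only)[:5]}"
        )

    feat = feat.set_index("subject_id")
    # validate the header before touching values
    for c in feat.columns:
        FeatureName.from_column(c)
    for col in feat.columns:
        numeric = pd.to_numeric(feat[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            sid = feat.index[bad.to_numpy()][0]
            raise ValidationError(
                f"missing/non-numeric value for subject {sid}, feature {col}"
            )
        feat[col] = numeric

    cog_cols = [c for c in COGNITIVE_TESTS if c in phen.columns]
    subjects = []
    for _, row in phen.iterrows():
        scores = {}
        for c in cog_cols:
            val = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.isna(val):
                raise ValidationError(
                    f"missing cognitive score {c} for subject {row['subject_id']}"
                )
            scores[c] = float(val)
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=int(row["diagnosis"]),
                sex=int(row["sex"]),
                age=float(row["age"]),
                education=float(row["education"]),
                cognitive_scores=scores,
            )
        )
    subjects.sort(key=lambda s: s.subject_id)
    feat = feat.loc[[s.subject_id for s in subjects]]
    return Cohort(subjects, feat)


def write_cohort(
    cohort: Cohort, feature_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write the two cohort files; round-trips through :func:`load_cohort`."""
    if cohort.n_subjects == 0:
        raise ValidationError("refusing to write an empty cohort")
    sep = "\t" if str(feature_path).endswith((".tsv", ".txt")) else ","
    table = cohort.table.copy()
    table.index.name = "subject_id"
    table.to_csv(feature_path, sep=sep, float_format="%.17g")

    cog_cols = sorted(
        {t for s in cohort.subjects for t in s.cognitive_scores},
        key=lambda t: COGNITIVE_TESTS.index(t) if t in COGNITIVE_TESTS else 99,
    )
    rows = []
    for s in cohort.subjects:
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "diagnosis": s.diagnosis,
            "sex": s.sex,
            "age": s.age,
            "education": s.education,
        }
        for c in cog_cols:
            row[c] = s.cognitive_scores[c]
        rows.append(row)
    sep = "\t" if str(phenotype_path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows).to_csv(
        phenotype_path, sep=sep, index=False, float_format="%.17g"
    )
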