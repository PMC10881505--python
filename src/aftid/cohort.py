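"""Cohort data model: records, covariate codings, validation and descriptives.

A semi-competing-risks cohort has one row per patient with a non-terminal
event (disease recurrence) that can be censored by the terminal event
(death), but not vice versa.  The observed pair is ``(y1, d1)`` for the
recurrence process and ``(y2, d2)`` for death, in months since surgery.

Conventions (one canonical dialect, enforced by the reader):

* ``y1 > 0``, ``y2 > 0`` and ``y1 <= y2``;
* ``d1 = 0`` implies ``y1 = y2`` — when the recurrence process is censored,
  whether by death or end of study, the recurrence clock stops at ``y2``;
* death without recurrence is stored as ``y1 = y2, d1 = 0, d2 = 1``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SemiCompetingRecord",
    "CovariateCoding",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "DEFAULT_CODINGS",
    "COHORT_COLUMNS",
    "percentage",
    "read_cohort_csv",
    "write_cohort_csv",
    "dataset_from_frame",
    "describe_cohort",
    "check_sample_size",
    "encode_design",
    "build_design",
]


class SchemaError(ValueError):
    """The table does not conform to the cohort CSV schema."""


class ValidationError(ValueError):
    """A record violates a cohort invariant."""


#: time columns are stored at this fixed decimal precision in the CSV dialect
TIME_DECIMALS = 4


@dataclass(frozen=True)
class SemiCompetingRecord:
    """One patient's observed semi-competing-risks outcome and covariates."""

    id: str
    y1: float
    d1: int
    y2: float
    d2: int
    covariates: Mapping[str, int]

    def validate(self) -> None:
        if not (self.y1 > 0 and self.y2 > 0):
            raise ValidationError(f"record {self.id}: times must be positive (y1>0, y2>0)")
        if self.y1 > self.y2:
            raise ValidationError(f"record {self.id}: y1 <= y2 violated")
        if self.d1 not in (0, 1) or self.d2 not in (0, 1):
            raise ValidationError(f"record {self.id}: indicators must be 0 or 1")
        if self.d1 == 0 and self.y1 != self.y2:
            raise ValidationError(f"record {self.id}: d1=0 implies y1=y2")


@dataclass(frozen=True)
class CovariateCoding:
    """How one covariate enters a design matrix.

    ``trend`` maps the ordered levels to consecutive integer scores 1..K so a
    single coefficient captures a per-level multiplicative effect; ``dummy``
    expands K levels into K-1 indicators with the referent omitted; ``binary``
    passes the 0/1 code through unchanged.
    """

    name: str
    levels: tuple[int, ...]
    scheme: str  # {"trend", "dummy", "binary"}
    referent: int | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("trend", "dummy", "binary"):
            raise ValueError(f"unknown coding scheme {self.scheme!r}")
        if self.scheme == "dummy" and self.referent is None:
            raise ValueError(f"dummy coding for {self.name!r} needs a referent level")
        if self.labels is not None and len(self.labels) != len(self.levels):
            raise ValueError(f"labels/levels length mismatch for {self.name!r}")

    def label(self, level: int) -> str:
        if self.labels is None:
            return str(level)
        return self.labels[self.levels.index(level)]

    def columns(self) -> list[str]:
        """Design column names this coding produces."""
        if self.scheme in ("trend", "binary"):
            return [self.name]
        return [f"{self.name}_{self.label(lv)}" for lv in self.levels if lv != self.referent]

    def expand(self, codes: np.ndarray) -> np.ndarray:
        """Map raw integer codes to design columns (n x k array)."""
        codes = np.asarray(codes)
        bad = ~np.isin(codes, self.levels)
        if bad.any():
            raise ValidationError(
                f"covariate {self.name!r}: unknown level(s) {sorted(set(codes[bad].tolist()))}"
            )
        if self.scheme == "binary":
            return codes.reshape(-1, 1).astype(float)
        if self.scheme == "trend":
            # scores 1..K in level order, independent of the raw codes
            score = {lv: i + 1 for i, lv in enumerate(self.levels)}
            return np.vectorize(score.get)(codes).reshape(-1, 1).astype(float)
        cols = [
            (codes == lv).astype(float) for lv in self.levels if lv != self.referent
        ]
        return np.column_stack(cols)


# Cohort CSV schema: exact header names and admissible codes.
COVARIATE_LEVELS: dict[str, tuple[int, ...]] = {
    "age_group": (1, 2, 3),
    "gender": (0, 1),
    "bmi_group": (1, 2, 3),
    "grade": (1, 2, 3),
    "tumor_size_group": (1, 2, 3),
    "chemo_group": (0, 1, 2),
    "stage": (1, 2),
    "site": (1, 2),
    "stage_site": (1, 2, 3, 4),
    "radiotherapy": (0, 1),
    "chemotherapy": (0, 1),
    "morphology": (0, 1),
    "metastasis": (0, 1),
    "pt_stage": (1, 2, 3, 4),
    "pn_stage": (1, 2, 3, 4),
}

COHORT_COLUMNS: list[str] = ["id", "y1", "d1", "y2", "d2", *COVARIATE_LEVELS]

STAGE_SITE_LABELS = ("Early_RC", "Early_CC", "Adv_RC", "Adv_CC")

DEFAULT_CODINGS: list[CovariateCoding] = [
    CovariateCoding("age_group", (1, 2, 3), "trend", labels=("le50", "51to70", "gt70")),
    CovariateCoding("gender", (0, 1), "binary", labels=("female", "male")),
    CovariateCoding("bmi_group", (1, 2, 3), "trend", labels=("normal", "overweight", "obese")),
    CovariateCoding("grade", (1, 2, 3), "dummy", referent=1, labels=("well", "moderate", "poor")),
    CovariateCoding("tumor_size_group", (1, 2, 3), "trend", labels=("lt4", "4to7", "ge7")),
    CovariateCoding("chemo_group", (0, 1, 2), "trend", labels=("none", "1to6", "gt6")),
    CovariateCoding("stage", (1, 2), "trend", labels=("early", "advanced")),
    CovariateCoding("site", (1, 2), "trend", labels=("rectum", "colon")),
    CovariateCoding("stage_site", (1, 2, 3, 4), "dummy", referent=1, labels=STAGE_SITE_LABELS),
    CovariateCoding("radiotherapy", (0, 1), "binary"),
    CovariateCoding("chemotherapy", (0, 1), "binary"),
    CovariateCoding("morphology", (0, 1), "binary"),
    CovariateCoding("metastasis", (0, 1), "binary"),
    CovariateCoding("pt_stage", (1, 2, 3, 4), "trend"),
    CovariateCoding("pn_stage", (1, 2, 3, 4), "trend"),
]

# Covariates entering the default multivariable designs (besides the
# stage/site terms, which depend on the model variant).
BASE_MODEL_COVARIATES = ["age_group", "gender", "chemo_group", "grade", "tumor_size_group"]


@dataclass
class Dataset:
    """Validated cohort: records plus the covariate codings in force."""

    records: list[SemiCompetingRecord]
    codings: list[CovariateCoding] = field(default_factory=lambda: list(DEFAULT_CODINGS))

    def __post_init__(self) -> None:
        names = None
        for rec in self.records:
            rec.validate()
            recnames = set(rec.covariates)
            if names is None:
                names = recnames
            elif recnames != names:
                raise ValidationError(f"record {rec.id}: covariate names differ across records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def coding(self, name: str) -> CovariateCoding:
        for c in self.codings:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"id": rec.id, "y1": rec.y1, "d1": rec.d1, "y2": rec.y2, "d2": rec.d2}
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(y1, d1, y2, d2) as numpy arrays in record order."""
        y1 = np.array([r.y1 for r in self.records], dtype=float)
        d1 = np.array([r.d1 for r in self.records], dtype=int)
        y2 = np.array([r.y2 for r in self.records], dtype=float)
        d2 = np.array([r.d2 for r in self.records], dtype=int)
        return y1, d1, y2, d2

    def covariate(self, name: str) -> np.ndarray:
        return np.array([r.covariates[name] for r in self.records], dtype=int)


def percentage(count: int, n: int) -> float:
    """100*count/n rounded half-up to one decimal, as printed in reports."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float((Decimal(100 * count) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def read_cohort_csv(path, codings: Sequence[CovariateCoding] | None = None) -> Dataset:
    """Read and validate a cohort CSV in the canonical schema.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` naming the row id and the violated rule.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    return dataset_from_frame(frame, codings)


def dataset_from_frame(frame: pd.DataFrame, codings: Sequence[CovariateCoding] | None = None) -> Dataset:
    codings = list(codings) if codings is not None else list(DEFAULT_CODINGS)
    cov_names = [c.name for c in codings]
    required = ["id", "y1", "d1", "y2", "d2", *cov_names]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    records = []
    for _, row in frame.iterrows():
        rid = str(row["id"])
        for col in required[1:]:
            if pd.isna(row[col]):
                raise ValidationError(f"record {rid}: missing value in column {col!r}")
        covs = {}
        for c in codings:
            val = int(row[c.name])
            if val not in c.levels:
                raise ValidationError(
                    f"record {rid}: covariate {c.name!r} has unknown level {val}"
                )
            covs[c.name] = val
        rec = SemiCompetingRecord(
            id=rid,
            y1=float(row["y1"]),
            d1=int(row["d1"]),
            y2=float(row["y2"]),
            d2=int(row["d2"]),
            covariates=covs,
        )
        rec.validate()
        records.append(rec)
    return Dataset(records, codings)


def write_cohort_csv(ds: Dataset, path) -> None:
    """Write the canonical cohort CSV (times at fixed decimal precision)."""
    cov_names = [c.name for c in ds.codings]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "y1", "d1", "y2", "d2", *cov_names])
        for rec in ds.records:
            writer.writerow(
                [
                    rec.id,
                    f"{rec.y1:.{TIME_DECIMALS}f}",
                    rec.d1,
                    f"{rec.y2:.{TIME_DECIMALS}f}",
                    rec.d2,
                    *[rec.covariates[n] for n in cov_names],
                ]
            )


def describe_cohort(ds: Dataset) -> pd.DataFrame:
    """Frequency table: per covariate level, count and percentage of n.

    Also reports the recurrence and death event counts.  Percentages are
    100*count/n rounded half-up to one decimal; within each covariate the
    counts sum to n.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    n = len(ds)
    rows = []
    _, d1, _, d2 = ds.arrays()
    rows.append({"covariate": "recurrence", "level": "yes", "count": int(d1.sum()),
                 "percent": percentage(int(d1.sum()), n)})
    rows.append({"covariate": "death", "level": "yes", "count": int(d2.sum()),
                 "percent": percentage(int(d2.sum()), n)})
    for coding in ds.codings:
        codes = ds.covariate(coding.name)
        for lv in coding.levels:
            cnt = int((codes == lv).sum())
            rows.append(
                {
                    "covariate": coding.name,
                    "level": coding.label(lv),
                    "count": cnt,
                    "percent": percentage(cnt, n),
                }
            )
    return pd.DataFrame(rows)


def check_sample_size(n: int, k: int) -> str:
    """Sample-size heuristic: adequate iff n >= 15 observations per risk factor."""
    if k < 1:
        raise ValueError("number of risk factors k must be >= 1")
    if n < 0:
        raise ValueError("n must be nonnegative")
    return "adequate" if n >= 15 * k else "inadequate"


MODEL_VARIANTS = ("stage_site_composite", "interaction")


def build_design(
    frame: pd.DataFrame,
    codings: Sequence[CovariateCoding],
    model_variant: str = "stage_site_composite",
    extra_columns: Mapping[str, np.ndarray] | None = None,
    check_rank: bool = True,
) -> pd.DataFrame:
    """Design matrix (no intercept column) for one model variant.

    ``stage_site_composite`` codes the four stage-by-site groups as three
    dummies against the Early_RC referent; ``interaction`` uses trend-coded
    stage and site plus their product.  The same design is used for all
    three transitions.  The intercept is carried by the error location of
    each transition, not by a column here.
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model_variant!r}")
    coding_by_name = {c.name: c for c in codings}
    blocks: list[pd.DataFrame] = []

    def add(coding: CovariateCoding) -> None:
        mat = coding.expand(frame[coding.name].to_numpy())
        blocks.append(pd.DataFrame(mat, columns=coding.columns(), index=frame.index))

    for name in BASE_MODEL_COVARIATES:
        add(coding_by_name[name])
    if model_variant == "stage_site_composite":
        add(coding_by_name["stage_site"])
    else:
        stage = coding_by_name["stage"].expand(frame["stage"].to_numpy())[:, 0]
        site = coding_by_name["site"].expand(frame["site"].to_numpy())[:, 0]
        blocks.append(
            pd.DataFrame(
                {"stage": stage, "site": site, "stage_x_site": stage * site},
                index=frame.index,
            )
        )
    if extra_columns:
        blocks.append(pd.DataFrame(dict(extra_columns), index=frame.index))
    X = pd.concat(blocks, axis=1)
    if check_rank:
        arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        if np.linalg.matrix_rank(arr) < arr.shape[1]:
            raise ValueError("design matrix (with intercept) is rank deficient")
    return X


def encode_design(
    ds: Dataset,
    model_variant: str = "stage_site_composite",
    extra_columns: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Design matrix for the cohort; identical across the three transitions."""
    return build_design(ds.to_frame(), ds.codings, model_variant, extra_columns)
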