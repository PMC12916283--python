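"""Cohort data model, CSV I/O, validation, and the rating-integration rule.

A cohort is one row per subject: follow-up time in months, a binary
event indicator (bipolar-spectrum disorder onset), and baseline
predictors — demographics, diagnosis and medication-class flags,
psychopathology scale totals, and the 31 BPSS-FP symptom items, each
carried as an ordinal severity (0–6) and a binary prevalence flag.

Missing predictor values are preserved through I/O and exposed via a
missingness mask; nothing in this module imputes. Ordinal severities
enter downstream models as numeric covariates, prevalence flags as 0/1,
and categorical columns (race) as one-hot indicators with the largest
observed category as reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_CODES",
    "BPSSItem",
    "CohortTable",
    "default_manifest",
    "read_manifest",
    "write_manifest",
    "read_cohort",
    "write_cohort",
    "integrate_ratings",
]

#: The 31 BPSS-FP item codes: Mania, Depression and General symptom indices.
ITEM_CODES: tuple[str, ...] = tuple(
    [f"M{i}" for i in range(1, 11)]
    + [f"D{i}" for i in range(1, 13)]
    + [f"G{i}" for i in range(1, 10)]
)

SEVERITY_MIN, SEVERITY_MAX = 0, 6

OUTCOME_COLUMNS = ("subject_id", "time_months", "event")

VALID_KINDS = ("binary", "continuous", "ordinal", "categorical")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class BPSSItem:
    """One BPSS-FP item rating: ordinal severity 0–6 plus a binary
    prevalence flag (symptom present at interview threshold). Either
    field may be missing (None/NaN)."""

    code: str
    severity: float | None = None
    prevalence: float | None = None

    def __post_init__(self):
        if self.code not in ITEM_CODES:
            raise ValueError(f"unknown BPSS item code {self.code!r}")
        sev, prev = self.severity, self.prevalence
        if not _is_missing(sev):
            if not float(sev).is_integer() or not (SEVERITY_MIN <= sev <= SEVERITY_MAX):
                raise ValueError(
                    f"item {self.code}: severity {sev!r} outside ordinal scale 0–6"
                )
        if not _is_missing(prev):
            if prev not in (0, 1, 0.0, 1.0):
                raise ValueError(f"item {self.code}: prevalence {prev!r} not in {{0,1}}")
        if not _is_missing(sev) and not _is_missing(prev):
            if prev == 1 and sev < 1:
                raise ValueError(
                    f"item {self.code}: prevalence=1 requires severity >= 1"
                )


def default_manifest() -> dict[str, str]:
    """Predictor manifest for the standard cohort layout: name -> kind."""
    manifest: dict[str, str] = {
        "age_years": "continuous",
        "sex_male": "binary",
        "race": "categorical",
        "madrs_total": "continuous",
        "cgi_s": "continuous",
        "gaf_current": "continuous",
        "gaf_high": "continuous",
        "gaf_low": "continuous",
        "ymrs_total": "continuous",
    }
    for dx in (
        "dx_persistent_depressive",
        "dx_mdd_single",
        "dx_mdd_recurrent",
        "dx_ptsd",
        "dx_adhd",
        "dx_generalized_anxiety",
        "dx_panic",
        "dx_odd",
        "dx_cannabis_use",
        "dx_attenuated_psychosis",
    ):
        manifest[dx] = "binary"
    for med in (
        "med_antipsychotic",
        "med_antidepressant",
        "med_mood_stabilizer",
        "med_lithium",
        "med_anxiolytic",
        "med_adhd",
    ):
        manifest[med] = "binary"
    for code in ITEM_CODES:
        manifest[f"sev_{code}"] = "ordinal"
        manifest[f"prev_{code}"] = "binary"
    return manifest


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the data model."""


class CohortTable:
    """Subjects x (outcome, predictors) with an explicit missingness mask.

    Parameters
    ----------
    df : DataFrame with columns ``subject_id``, ``time_months``, ``event``
        plus every predictor named in ``manifest``.
    manifest : mapping predictor name -> kind
        Kinds: ``binary``, ``continuous``, ``ordinal``, ``categorical``.
    horizon_months : administrative follow-up cap; times must not exceed it.
    """

    def __init__(self, df: pd.DataFrame, manifest: Mapping[str, str], *,
                 horizon_months: float = 60.0, validate: bool = True):
        self.df = df.reset_index(drop=True)
        self.manifest = dict(manifest)
        self.horizon_months = float(horizon_months)
        if validate:
            self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.df["time_months"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.manifest)

    @property
    def predictors(self) -> pd.DataFrame:
        return self.df[self.predictor_names]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask over predictor columns (True = missing)."""
        return self.df[self.predictor_names].isna()

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.manifest),
                           horizon_months=self.horizon_months, validate=False)

    def subset(self, index) -> "CohortTable":
        """Row subset by positional index; preserves column order, skips
        re-validation (rows were already validated)."""
        sub = self.df.iloc[np.asarray(index)].reset_index(drop=True)
        return CohortTable(sub, dict(self.manifest),
                           horizon_months=self.horizon_months, validate=False)

    # -- model matrix ------------------------------------------------------
    def design_frame(self) -> pd.DataFrame:
        """Numeric predictor frame for model fitting.

        Binary/ordinal/continuous columns pass through as floats;
        categorical columns are expanded to one-hot indicators with the
        largest observed category as the reference level. Missing cells
        stay NaN (one-hot rows for a missing categorical are all-NaN).
        """
        parts: list[pd.DataFrame | pd.Series] = []
        for name, kind in self.manifest.items():
            col = self.df[name]
            if kind == "categorical":
                observed = col.dropna()
                if observed.empty:
                    continue
                levels = observed.value_counts()
                reference = levels.index[0]
                for level in levels.index:
                    if level == reference:
                        continue
                    ind = (col == level).astype(float)
                    ind[col.isna()] = np.nan
                    ind.name = f"{name}_{_slug(level)}"
                    parts.append(ind)
            else:
                parts.append(col.astype(float))
        return pd.concat(parts, axis=1)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        for col in OUTCOME_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing outcome column {col!r}")
        for name, kind in self.manifest.items():
            if name not in df.columns:
                raise CohortValidationError(f"manifest predictor {name!r} absent from table")
            if kind not in VALID_KINDS:
                raise CohortValidationError(f"predictor {name!r}: unknown kind {kind!r}")
        extra = [c for c in df.columns
                 if c not in OUTCOME_COLUMNS and c not in self.manifest]
        if extra:
            raise CohortValidationError(
                f"columns not covered by the manifest: {extra}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"duplicate subject_id {dup!r}")
        t = df["time_months"]
        if t.isna().any() or (t <= 0).any():
            bad = df.index[t.isna() | (t <= 0)][0]
            raise CohortValidationError(f"row {bad}: time_months must be positive")
        if (t > self.horizon_months + 1e-9).any():
            bad = df.index[t > self.horizon_months + 1e-9][0]
            raise CohortValidationError(
                f"row {bad}: time_months exceeds horizon {self.horizon_months}")
        ev = df["event"]
        if ev.isna().any() or ~ev.isin([0, 1]).all():
            bad = df.index[ev.isna() | ~ev.isin([0, 1])][0]
            raise CohortValidationError(f"row {bad}: event must be 0 or 1")
        for name, kind in self.manifest.items():
            col = df[name]
            obs = col.dropna()
            if kind == "binary" and not obs.isin([0, 1]).all():
                bad = obs.index[~obs.isin([0, 1])][0]
                raise CohortValidationError(
                    f"row {bad}, column {name!r}: binary value {df.at[bad, name]!r}")
            if kind == "ordinal":
                ok = obs.isin(range(SEVERITY_MIN, SEVERITY_MAX + 1))
                if not ok.all():
                    bad = obs.index[~ok][0]
                    raise CohortValidationError(
                        f"row {bad}, column {name!r}: severity {df.at[bad, name]!r} "
                        f"outside ordinal scale {SEVERITY_MIN}–{SEVERITY_MAX}")
        # prevalence=1 implies severity >= 1 when both observed
        for code in ITEM_CODES:
            sev_c, prev_c = f"sev_{code}", f"prev_{code}"
            if sev_c in df.columns and prev_c in df.columns:
                both = df[sev_c].notna() & df[prev_c].notna()
                viol = both & (df[prev_c] == 1) & (df[sev_c] < 1)
                if viol.any():
                    bad = df.index[viol][0]
                    raise CohortValidationError(
                        f"row {bad}, item {code}: prevalence=1 with severity 0")


def _slug(value) -> str:
    return str(value).strip().lower().replace(" ", "_").replace("/", "_")


# -- manifest I/O ----------------------------------------------------------

def write_manifest(manifest: Mapping[str, str], path: str | Path) -> None:
    """Write a key=value manifest file (one predictor per line)."""
    lines = [f"{name}={kind}" for name, kind in manifest.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path: str | Path) -> dict[str, str]:
    manifest: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"manifest line {line!r} is not key=value")
        name, kind = (s.strip() for s in line.split("=", 1))
        manifest[name] = kind
    return manifest


# -- cohort I/O ------------------------------------------------------------

def read_cohort(path: str | Path, manifest: Mapping[str, str], *,
                horizon_months: float = 60.0) -> CohortTable:
    """Read and validate a cohort CSV (RFC-4180, UTF-8, header row).

    Missing cells are recorded in the mask, never filled. Any violation
    of the data model (missing outcome columns, out-of-range severity,
    duplicate ids...) raises :class:`CohortValidationError` naming the
    offending row and column.
    """
    df = pd.read_csv(path)
    cat_cols = [n for n, k in dict(manifest).items() if k == "categorical"]
    for c in cat_cols:
        if c in df.columns:
            df[c] = df[c].astype("string").astype(object)
    return CohortTable(df, manifest, horizon_months=horizon_months)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV; round-trips with :func:`read_cohort`."""
    table.df.to_csv(path, index=False)


# -- rating integration ----------------------------------------------------

def integrate_ratings(
    patient: Mapping[str, BPSSItem],
    caregiver: Mapping[str, BPSSItem],
) -> dict[str, BPSSItem]:
    """Merge patient- and caregiver-based BPSS-FP ratings per item by
    taking the higher severity and the higher prevalence flag.

    The rule assumes symptoms are more likely forgotten by one informant
    than invented by the other, so the stronger observation carries. If
    only one side observed a field, that observation carries; if both
    are missing the integrated field is missing. The operation is
    commutative, idempotent, and never decreases an observed rating.
    """
    if set(patient) != set(caregiver):
        raise ValueError("patient and caregiver ratings cover different item sets")
    out: dict[str, BPSSItem] = {}
    for code in patient:
        p, c = patient[code], caregiver[code]
        if p.code != code or c.code != code:
            raise ValueError(f"item code mismatch under key {code!r}")
        out[code] = BPSSItem(
            code=code,
            severity=_max_observed(p.severity, c.severity),
            prevalence=_max_observed(p.prevalence, c.prevalence),
        )
    return out


def _max_observed(a, b):
    if _is_missing(a) and _is_missing(b):
        return None
    if _is_missing(a):
        return b
    if _is_missing(b):
        return a
    return max(a, b)
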