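"""Domain types and CSV I/O for wristband exposure data.

Concentrations are reported in ng/g silicone. A value of 0 encodes a
non-detect: the chemical was assayed but not found above the method's
quantitation limit. Zeros are retained (not substituted or dropped) in all
descriptive statistics and downstream analyses, matching the convention of
reporting interquartile ranges with lower bounds of 0 for chemicals detected
in fewer than 75% of samples.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SEASONS",
    "ChemicalRecord",
    "WearRecord",
    "ExposureMatrix",
    "CovariateTable",
    "ValidationError",
    "season_of",
    "read_exposure_csv",
    "write_exposure_csv",
    "read_chemical_metadata",
    "write_chemical_metadata",
    "read_covariates",
    "write_covariates",
]

#: Chemical category labels used by the broad GC-MS screening panel.
CATEGORIES = frozenset(
    {
        "chemicals in commerce",
        "personal care products",
        "pesticides",
        "flame retardants",
        "PAHs",
        "consumer products",
        "pharmacological",
    }
)

SEASONS = ("winter", "spring", "summer", "fall")

WRISTBAND_SIZES = ("regular", "small")

#: Allowed covariate levels, keyed by column name.  ``None`` marks a
#: continuous variable.
COVARIATE_LEVELS: dict[str, tuple[str, ...] | None] = {
    "age_years": None,
    "bmi": None,
    "education": ("less than college graduate", "college graduate", "any post-graduate"),
    "marital": ("married", "unmarried"),
    "race_ethnicity": ("White non-Hispanic", "other"),
    "parity": ("0", ">=1"),
    "smoke_exposure": ("none", "first- or second-hand"),
    "nail_polish_use": ("yes", "no"),
    "handwashing_per_day": None,
    "gardening": ("yes", "no"),
}

_CASN_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and category membership of one assayed chemical.

    A chemical may belong to several categories (e.g. di-n-butyl phthalate
    is simultaneously a chemical in commerce, a personal-care-product
    ingredient, and a pesticide formulation component).
    """

    chemical_id: str
    name: str
    casn: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not _CASN_RE.match(self.casn):
            raise ValidationError(f"invalid CAS number {self.casn!r} for {self.name!r}")
        if not self.categories:
            raise ValidationError(f"chemical {self.name!r} has no categories")
        unknown = set(self.categories) - CATEGORIES
        if unknown:
            raise ValidationError(
                f"chemical {self.name!r} has unknown categories {sorted(unknown)}"
            )


@dataclass(frozen=True)
class WearRecord:
    """Wear metadata for one wristband deployment."""

    start_date: _dt.date
    duration_days: float
    gestational_age_start: float
    wristband_size: str
    season: str | None = None

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValidationError(f"duration_days must be positive, got {self.duration_days}")
        if self.wristband_size not in WRISTBAND_SIZES:
            raise ValidationError(f"unknown wristband size {self.wristband_size!r}")
        if self.season is None:
            object.__setattr__(self, "season", season_of(self.start_date))
        elif self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")


def season_of(date: _dt.date) -> str:
    """Meteorological season of a calendar date.

    Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov fall.  Applied
    to the date the wristband was first worn.
    """
    return {
        12: "winter", 1: "winter", 2: "winter",
        3: "spring", 4: "spring", 5: "spring",
        6: "summer", 7: "summer", 8: "summer",
        9: "fall", 10: "fall", 11: "fall",
    }[date.month]


# sample-level metadata columns, in canonical CSV order
_SAMPLE_COLS = [
    "participant_id",
    "timepoint",
    "batch",
    "start_date",
    "duration_days",
    "gestational_age_start",
    "wristband_size",
    "season",
]


@dataclass
class ExposureMatrix:
    """Participant x chemical concentration matrix with sample metadata.

    ``values`` is indexed by sample (one row per participant-timepoint) with
    one float column per chemical; ``samples`` carries the per-sample batch,
    timepoint and wear metadata on the same index.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.samples.index):
            raise ValidationError("values and samples must share an index")
        neg = np.argwhere(self.values.to_numpy() < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative concentration at sample {self.values.index[r]!r}, "
                f"chemical {self.values.columns[c]!r}"
            )
        pairs = self.samples[["participant_id", "timepoint"]]
        dup = pairs.duplicated()
        if dup.any():
            p, t = pairs[dup].iloc[0]
            raise ValidationError(f"duplicate sample for participant {p!r} at timepoint {t!r}")
        if self.samples["batch"].isna().any():
            missing = self.samples.index[self.samples["batch"].isna()][0]
            raise ValidationError(f"sample {missing!r} has no batch label")

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.samples["participant_id"])

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset_timepoint(self, timepoint: str) -> "ExposureMatrix":
        mask = self.samples["timepoint"] == timepoint
        return ExposureMatrix(self.values.loc[mask].copy(), self.samples.loc[mask].copy())

    def subset_chemicals(self, chemical_ids: list[str]) -> "ExposureMatrix":
        return ExposureMatrix(self.values[list(chemical_ids)].copy(), self.samples.copy())


@dataclass
class CovariateTable:
    """Per-participant covariates; missing values are pd.NA / NaN.

    Missingness is preserved exactly as read — imputation is an explicit,
    separate analysis step.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col, levels in COVARIATE_LEVELS.items():
            if col not in self.data.columns:
                raise ValidationError(f"covariate table missing column {col!r}")
            if levels is not None:
                vals = self.data[col].dropna()
                bad = set(vals) - set(levels)
                if bad:
                    raise ValidationError(
                        f"covariate {col!r} has disallowed value(s) {sorted(bad)!r}; "
                        f"allowed: {levels}"
                    )
            else:
                # continuous columns must be numeric (NaN allowed)
                self.data[col] = pd.to_numeric(self.data[col], errors="raise")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# CSV I/O.  Canonical dialect: comma-separated, UTF-8, header row, '.' decimal.
# ---------------------------------------------------------------------------

def read_chemical_metadata(path) -> list[ChemicalRecord]:
    """Read the chemical metadata CSV (chemical_id, name, casn, categories).

    ``categories`` is a ``;``-separated list of category labels.
    """
    df = pd.read_csv(path, dtype=str)
    records = []
    for _, row in df.iterrows():
        cats = frozenset(c.strip() for c in row["categories"].split(";") if c.strip())
        records.append(
            ChemicalRecord(
                chemical_id=row["chemical_id"],
                name=row["name"],
                casn=row["casn"],
                categories=cats,
            )
        )
    return records


def write_chemical_metadata(records: list[ChemicalRecord], path) -> None:
    rows = [
        {
            "chemical_id": r.chemical_id,
            "name": r.name,
            "casn": r.casn,
            "categories": ";".join(sorted(r.categories)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_exposure_csv(path, metadata_path) -> tuple[ExposureMatrix, list[ChemicalRecord]]:
    """Read a wide sample x chemical concentration CSV plus chemical metadata.

    One row per (participant, timepoint) sample; metadata must cover every
    chemical column.  Negative concentrations and duplicate samples are
    rejected with the offending cell/row named.
    """
    records = read_chemical_metadata(metadata_path)
    known = {r.chemical_id for r in records}
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "timepoint": str, "batch": str},
        float_precision="round_trip",
    )
    chem_cols = [c for c in df.columns if c not in _SAMPLE_COLS]
    unknown = [c for c in chem_cols if c not in known]
    if unknown:
        raise ValidationError(f"chemicals missing from metadata: {unknown}")
    sample_id = df["participant_id"] + ":" + df["timepoint"]
    samples = df[_SAMPLE_COLS].copy()
    samples.index = pd.Index(sample_id, name="sample_id")
    samples["start_date"] = pd.to_datetime(samples["start_date"]).dt.date
    values = df[chem_cols].astype(float)
    values.index = samples.index
    matrix = ExposureMatrix(values, samples)
    used = [r for r in records if r.chemical_id in set(chem_cols)]
    return matrix, used


def write_exposure_csv(matrix: ExposureMatrix, path) -> None:
    out = matrix.samples.copy()
    for c in matrix.values.columns:
        out[c] = matrix.values[c]
    out.to_csv(path, index=False)


def read_covariates(path) -> CovariateTable:
    """Read a per-participant covariate CSV; blank cells mean missing."""
    df = pd.read_csv(path, dtype=str, float_precision="round_trip").set_index("participant_id")
    for col in ("age_years", "bmi", "handwashing_per_day"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    extra = [c for c in ("gestational_age_start", "season") if c in df.columns]
    for col in extra:
        if col == "gestational_age_start":
            df[col] = pd.to_numeric(df[col])
    return CovariateTable(df)


def write_covariates(table: CovariateTable, path) -> None:
    table.data.to_csv(path, index=True, index_label="participant_id")
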