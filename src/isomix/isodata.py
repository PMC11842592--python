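"""Domain types, CSV readers, delta-notation utilities and validation.

Two tidy CSV schemas are supported:

* consumers: ``sample_id,class,period,year,d13c,d15n`` with an optional
  ``lipid_extracted_n`` boolean column marking samples whose nitrogen
  values were measured on lipid-extracted tissue.
* prey: ``sample_id,taxon,group,region,period,year,d13c,d15n,pct_c,pct_n``
  (``group`` may be left empty and supplied later through a taxon map).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    """Raised when an operation receives values outside its domain."""


class SchemaError(ValueError):
    """Raised when a CSV is missing required columns."""


class ConfigurationError(ValueError):
    """Raised for incomplete mappings or coefficient tables."""


class DegenerateGroupError(ValueError):
    """Raised when a prey group cannot yield usable summary statistics."""


class Role(str, enum.Enum):
    CONSUMER = "consumer"
    PREY = "prey"


class Period(str, enum.Enum):
    P2000S = "2000s"
    P2020S = "2020s"


class SexAgeClass(str, enum.Enum):
    ADULT_MALE = "adult_male"
    ADULT_FEMALE = "adult_female"
    JUVENILE = "juvenile"


class Region(str, enum.Enum):
    UE = "UE"
    LE = "LE"
    NWGSL = "nwGSL"


#: Default year ranges accepted for each period (inclusive). Prey sampling
#: starts slightly earlier than consumer sampling in the first period.
PERIOD_YEARS: dict[Period, tuple[int, int]] = {
    Period.P2000S: (1995, 2003),
    Period.P2020S: (2015, 2020),
}

#: Plausibility bounds for tracer values; violations warn unless strict.
VALIDATION_BOUNDS = {"d13c": (-40.0, -10.0), "d15n": (0.0, 25.0)}


@dataclass(frozen=True)
class IsotopeSample:
    """A single specimen's tracer values plus metadata."""

    sample_id: str
    role: Role
    period: Period
    year: int
    d13c: float
    d15n: float
    taxon: str = ""
    group_label: str | None = None
    sex_age_class: SexAgeClass | None = None
    region: Region | None = None
    pct_c: float | None = None
    pct_n: float | None = None
    lipid_extracted_n: bool = False
    corrected: bool = False

    @property
    def tracers(self) -> np.ndarray:
        return np.array([self.d13c, self.d15n])


@dataclass(frozen=True)
class SourceSummary:
    """Per-group tracer mean/SD and elemental concentrations.

    ``mean``/``sd`` are length-2 arrays ordered (d13c, d15n); ``conc`` holds
    the mean elemental mass fractions (C, N) used for concentration
    dependence in the mixing model.
    """

    group_label: str
    period: Period
    n: int
    mean: np.ndarray
    sd: np.ndarray
    conc: np.ndarray
    conc_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        if self.n < 2:
            raise DegenerateGroupError(
                f"group {self.group_label!r}: n={self.n} < 2"
            )
        if np.any(self.sd <= 0):
            raise DegenerateGroupError(
                f"group {self.group_label!r}: non-positive tracer SD {self.sd}"
            )
        if np.any(self.conc <= 0) or np.any(self.conc > 1):
            raise InvalidInputError(
                f"group {self.group_label!r}: concentrations must lie in (0, 1], "
                f"got {self.conc}"
            )


@dataclass(frozen=True)
class TDFSpec:
    """Trophic discrimination factor (mean, SD) per tracer."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.sd < 0):
            raise InvalidInputError("TDF sd must be >= 0")


#: Muscle-tissue discrimination factors used by default (per-mil).
DEFAULT_TDF = TDFSpec(mean=np.array([1.3, 2.4]), sd=np.array([0.5, 0.5]))


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert an isotope ratio to per-mil delta notation.

    delta = (r_sample / r_standard - 1) * 1000.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(np.asarray(r_standard) <= 0):
        raise InvalidInputError("standard ratio must be positive")
    if np.any(r_sample < 0):
        raise InvalidInputError("sample ratio must be non-negative")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if np.any(np.asarray(r_standard) <= 0):
        raise InvalidInputError("standard ratio must be positive")
    out = (np.asarray(delta, dtype=float) / 1000.0 + 1.0) * r_standard
    return float(out) if out.ndim == 0 else out


_CONSUMER_REQUIRED = ["sample_id", "class", "period", "year", "d13c", "d15n"]
_PREY_REQUIRED = [
    "sample_id",
    "taxon",
    "region",
    "period",
    "year",
    "d13c",
    "d15n",
    "pct_c",
    "pct_n",
]

_TRUTHY = {"1", "true", "yes", "y"}


def _parse_period(raw: str) -> Period:
    token = str(raw).strip().lower().lstrip("p")
    for p in Period:
        if p.value.lower() == token:
            return p
    raise ValueError(f"unknown period {raw!r}")


def _parse_class(raw: str) -> SexAgeClass:
    token = str(raw).strip().lower()
    for c in SexAgeClass:
        if c.value == token:
            return c
    raise ValueError(f"unknown sex/age class {raw!r}")


def _validate_bounds(sample: IsotopeSample, row_no: int, strict: bool) -> None:
    for attr, (lo, hi) in VALIDATION_BOUNDS.items():
        value = getattr(sample, attr)
        if not lo <= value <= hi:
            msg = f"row {row_no}: {attr}={value} outside [{lo}, {hi}]"
            if strict:
                raise InvalidInputError(msg)
            logger.warning(msg)
    lo, hi = PERIOD_YEARS[sample.period]
    if not lo <= sample.year <= hi:
        msg = f"row {row_no}: year {sample.year} outside {sample.period.value} range"
        if strict:
            raise InvalidInputError(msg)
        logger.warning(msg)


def read_samples(
    path: str | Path,
    schema: Role | str,
    strict: bool = False,
) -> list[IsotopeSample]:
    """Read consumer or prey records from CSV.

    Rows that cannot be parsed are rejected with a row-numbered message;
    in non-strict mode rejections are logged and skipped, in strict mode the
    first failure raises. Missing required columns always raise
    :class:`SchemaError`.
    """
    schema = Role(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _CONSUMER_REQUIRED if schema is Role.CONSUMER else _PREY_REQUIRED
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    samples: list[IsotopeSample] = []
    n_rejected = 0
    for idx, row in frame.iterrows():
        row_no = int(idx) + 2  # header is line 1
        try:
            samples.append(_parse_row(row, schema))
            _validate_bounds(samples[-1], row_no, strict)
        except InvalidInputError:
            raise
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            msg = f"{path}: row {row_no} rejected: {exc}"
            if strict:
                raise InvalidInputError(msg) from exc
            logger.warning(msg)
    if not samples:
        logger.warning("%s: no valid %s rows parsed", path, schema.value)
    logger.info(
        "%s: parsed %d %s rows (%d rejected)", path, len(samples), schema.value, n_rejected
    )
    return samples


def _parse_row(row: pd.Series, schema: Role) -> IsotopeSample:
    def _float(col: str) -> float:
        raw = str(row[col]).strip()
        if raw == "":
            raise ValueError(f"missing value in column {col!r}")
        value = float(raw)
        if not math.isfinite(value):
            raise ValueError(f"non-finite value in column {col!r}")
        return value

    period = _parse_period(row["period"])
    year = int(str(row["year"]).strip())
    common = dict(
        sample_id=str(row["sample_id"]).strip(),
        period=period,
        year=year,
        d13c=_float("d13c"),
        d15n=_float("d15n"),
    )
    if schema is Role.CONSUMER:
        lipid = str(row.get("lipid_extracted_n", "")).strip().lower() in _TRUTHY
        return IsotopeSample(
            role=Role.CONSUMER,
            taxon="beluga",
            sex_age_class=_parse_class(row["class"]),
            lipid_extracted_n=lipid,
            **common,
        )
    region = Region(str(row["region"]).strip())
    group = str(row.get("group", "")).strip() or None
    return IsotopeSample(
        role=Role.PREY,
        taxon=str(row["taxon"]).strip(),
        group_label=group,
        region=region,
        pct_c=_float("pct_c"),
        pct_n=_float("pct_n"),
        **common,
    )


def write_samples(samples: Sequence[IsotopeSample], path: str | Path) -> None:
    """Write samples back to the tidy CSV schema they were read from."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "role": s.role.value,
                "taxon": s.taxon,
                "group": s.group_label or "",
                "class": s.sex_age_class.value if s.sex_age_class else "",
                "region": s.region.value if s.region else "",
                "period": s.period.value,
                "year": s.year,
                "d13c": s.d13c,
                "d15n": s.d15n,
                "pct_c": "" if s.pct_c is None else s.pct_c,
                "pct_n": "" if s.pct_n is None else s.pct_n,
                "lipid_extracted_n": int(s.lipid_extracted_n),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def summarize_sources(
    prey: Iterable[IsotopeSample],
    grouping: Mapping[str, str] | None,
    period: Period | str,
) -> list[SourceSummary]:
    """Aggregate prey samples from one period into per-group source summaries.

    ``grouping`` maps taxon to group label; if None, each sample's own
    ``group_label`` is used. SDs use the n-1 denominator; concentrations are
    mean pct_c/pct_n divided by 100.
    """
    period = Period(period) if not isinstance(period, Period) else period
    by_group: dict[str, list[IsotopeSample]] = {}
    for s in prey:
        if s.period != period:
            continue
        if grouping is not None:
            if s.taxon not in grouping:
                raise ConfigurationError(f"taxon {s.taxon!r} not in grouping map")
            label = grouping[s.taxon]
        else:
            label = s.group_label
        if label is None:
            raise ConfigurationError(
                f"sample {s.sample_id!r} has no group label and no grouping map given"
            )
        by_group.setdefault(label, []).append(s)

    summaries = []
    for label in sorted(by_group):
        members = by_group[label]
        if len(members) < 2:
            raise DegenerateGroupError(
                f"group {label!r} has n={len(members)} < 2 in period {period.value}"
            )
        x = np.array([[m.d13c, m.d15n] for m in members])
        if any(m.pct_c is None or m.pct_n is None for m in members):
            raise ConfigurationError(f"group {label!r}: prey records lack pct_c/pct_n")
        conc_pct = np.array([[m.pct_c, m.pct_n] for m in members])
        summaries.append(
            SourceSummary(
                group_label=label,
                period=period,
                n=len(members),
                mean=x.mean(axis=0),
                sd=x.std(axis=0, ddof=1),
                conc=conc_pct.mean(axis=0) / 100.0,
                conc_sd=conc_pct.std(axis=0, ddof=1) / 100.0,
            )
        )
    return summaries


def sources_to_frame(sources: Sequence[SourceSummary]) -> pd.DataFrame:
    """Tabulate source summaries for CSV export."""
    return pd.DataFrame(
        {
            "group": [s.group_label for s in sources],
            "period": [s.period.value for s in sources],
            "n": [s.n for s in sources],
            "mean_d13c": [s.mean[0] for s in sources],
            "mean_d15n": [s.mean[1] for s in sources],
            "sd_d13c": [s.sd[0] for s in sources],
            "sd_d15n": [s.sd[1] for s in sources],
            "conc_c": [s.conc[0] for s in sources],
            "conc_n": [s.conc[1] for s in sources],
        }
    )
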