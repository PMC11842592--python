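"""Temporal and analytical corrections applied before diet modelling.

Two corrections are implemented:

* an additive d13C adjustment for the secular oceanic decline in 13C
  (fossil-fuel Suess effect) plus its temperature-dependent aquatic
  modulation (Laws effect), centered so the correction is exactly zero at
  a chosen reference year;
* a linear restoration of bulk d15N for samples whose nitrogen was
  measured on lipid-extracted tissue.

The drift model is a reconstruction of the regional-preset functional
form used by published correction software (exponential decline since a
pre-industrial epoch plus a slower linear temperature-mediated term); the
shipped North Atlantic constants are reconstructed defaults, editable via
JSON, not measured values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from isomix.isodata import (
    ConfigurationError,
    InvalidInputError,
    IsotopeSample,
    Period,
)

logger = logging.getLogger(__name__)

EPOCH_YEAR = 1850
YEAR_RANGE = (1850, 2025)

#: Cumulative decline amplitude / rate reconstructed for the North Atlantic
#: surface ocean: d(year) = -a*(exp(r*(year-1850)) - 1) - l*(year-1850).
NORTH_ATLANTIC_PRESET = {
    "suess_a": 0.0294,
    "suess_r": 0.0231,
    "laws_l": 0.0015,
}


@dataclass(frozen=True)
class SuessParams:
    """Regional drift parameters and the period's centering year."""

    region: str
    reference_year: int
    suess_rate_params: Mapping[str, float] = field(
        default_factory=lambda: dict(NORTH_ATLANTIC_PRESET)
    )

    @classmethod
    def from_json(cls, path: str | Path, region: str, reference_year: int) -> "SuessParams":
        presets = json.loads(Path(path).read_text())
        if region not in presets:
            raise ConfigurationError(f"no Suess preset for region {region!r}")
        return cls(region=region, reference_year=reference_year,
                   suess_rate_params=presets[region])


#: Centering years: the year with the highest sample size in each period.
REFERENCE_YEARS: dict[Period, int] = {Period.P2000S: 2002, Period.P2020S: 2020}


def _cumulative_decline(year: float, params: Mapping[str, float]) -> float:
    """Total d13C change (per-mil, <= 0) from the 1850 epoch to ``year``."""
    t = year - EPOCH_YEAR
    a = params["suess_a"]
    r = params["suess_r"]
    l = params["laws_l"]
    return -(a * (np.expm1(r * t))) - l * t


def suess_correction(year: int, params: SuessParams) -> float:
    """Additive d13C correction that centers a sample on the reference year.

    corrected d13c = raw d13c + correction. The correction is zero at the
    reference year and negative for earlier years (the environment was
    13C-richer then, so older samples are adjusted downward to be
    comparable with the reference year under the declining curve).
    """
    if not YEAR_RANGE[0] <= year <= YEAR_RANGE[1]:
        raise InvalidInputError(f"year {year} outside supported range {YEAR_RANGE}")
    p = params.suess_rate_params
    return float(
        _cumulative_decline(params.reference_year, p) - _cumulative_decline(year, p)
    )


@dataclass(frozen=True)
class N15RestorationModel:
    """Per-taxon linear coefficients restoring bulk d15N from
    lipid-extracted measurements: bulk = intercept + slope * measured."""

    coefficients: Mapping[str, tuple[float, float]]
    fallback: tuple[float, float] | None = (0.0, 1.0)

    def __post_init__(self) -> None:
        for taxon, (_, slope) in self.coefficients.items():
            if slope <= 0:
                raise ConfigurationError(f"taxon {taxon!r}: slope must be > 0")

    @classmethod
    def from_csv(cls, path: str | Path, fallback=(0.0, 1.0)) -> "N15RestorationModel":
        frame = pd.read_csv(path)
        coeffs = {
            str(r["taxon"]): (float(r["intercept"]), float(r["slope"]))
            for _, r in frame.iterrows()
        }
        return cls(coefficients=coeffs, fallback=fallback)

    @classmethod
    def identity(cls) -> "N15RestorationModel":
        return cls(coefficients={}, fallback=(0.0, 1.0))


def restore_bulk_d15n(
    d15n_lipid_extracted: float, taxon: str, model: N15RestorationModel
) -> float:
    """Apply the taxon's linear restoration; identity under (0, 1)."""
    if taxon in model.coefficients:
        intercept, slope = model.coefficients[taxon]
    elif model.fallback is not None:
        intercept, slope = model.fallback
    else:
        raise ConfigurationError(
            f"no d15N restoration coefficients for taxon {taxon!r} and no fallback"
        )
    return intercept + slope * d15n_lipid_extracted


def apply_corrections(
    samples: Iterable[IsotopeSample],
    params: SuessParams,
    n15model: N15RestorationModel | None = None,
) -> tuple[list[IsotopeSample], pd.DataFrame]:
    """Correct a sample collection; returns corrected samples + audit log.

    d13c is shifted by :func:`suess_correction`; d15n is restored only for
    samples flagged ``lipid_extracted_n``. Samples already carrying the
    ``corrected`` provenance flag are refused to prevent double-correction.
    """
    corrected: list[IsotopeSample] = []
    audit_rows = []
    for s in samples:
        if s.corrected:
            raise InvalidInputError(
                f"sample {s.sample_id!r} already corrected; refusing to re-correct"
            )
        c13 = suess_correction(s.year, params)
        new_d15n = s.d15n
        if s.lipid_extracted_n and n15model is not None:
            new_d15n = restore_bulk_d15n(s.d15n, s.taxon, n15model)
        corrected.append(
            replace(s, d13c=s.d13c + c13, d15n=new_d15n, corrected=True)
        )
        audit_rows.append(
            {
                "sample_id": s.sample_id,
                "year": s.year,
                "d13c_correction": c13,
                "d15n_before": s.d15n,
                "d15n_after": new_d15n,
                "n15_restored": bool(s.lipid_extracted_n and n15model is not None),
            }
        )
    return corrected, pd.DataFrame(audit_rows)
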