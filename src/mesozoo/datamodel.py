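"""Domain types shared across the biomass pipeline.

Records are lightweight dataclasses used at the validation boundary;
bulk processing happens on pandas DataFrames whose column contracts are
documented in ``mesozoo/data/DATA_DICTIONARY.md``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

VALID_HABITATS = frozenset({"coast", "bank", "trough"})
VALID_GROUPS = frozenset({"holoplankton", "meroplankton", "ichthyoplankton"})
VALID_SIZE_CLASSES = frozenset({"SMZ", "LMZ"})
VALID_SPLITS = frozenset({4, 8, 16})


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass(frozen=True)
class StationRecord:
    station_id: str
    depth: float  # m
    habitat: str

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError(f"station {self.station_id}: depth must be > 0")
        if self.habitat not in VALID_HABITATS:
            raise ValidationError(
                f"station {self.station_id}: habitat {self.habitat!r} not in {sorted(VALID_HABITATS)}"
            )


@dataclass(frozen=True)
class SamplingEvent:
    event_id: str
    calendar_date: _dt.date

    @property
    def day_of_year(self) -> int:
        return self.calendar_date.timetuple().tm_yday


@dataclass(frozen=True)
class TaxonRecord:
    """One row of the conversion-factor registry.

    carbon_factor is mg C per mg DW, energy_factor J per mg DW.
    cross_class_flag marks taxa whose size range spans both classes but
    whose biomass is assigned entirely to LMZ.
    """

    taxon_name: str
    plankton_group: str
    size_class: str
    carbon_factor: Optional[float]
    energy_factor: Optional[float]
    cross_class_flag: bool = False

    def __post_init__(self) -> None:
        if self.plankton_group not in VALID_GROUPS:
            raise ValidationError(f"{self.taxon_name}: bad plankton_group {self.plankton_group!r}")
        if self.size_class not in VALID_SIZE_CLASSES:
            raise ValidationError(f"{self.taxon_name}: bad size_class {self.size_class!r}")
        if self.carbon_factor is not None and not 0 < self.carbon_factor < 1:
            raise ValidationError(f"{self.taxon_name}: carbon_factor must be in (0, 1)")
        if self.energy_factor is not None and self.energy_factor <= 0:
            raise ValidationError(f"{self.taxon_name}: energy_factor must be > 0")


@dataclass(frozen=True)
class WeighingRecord:
    """One dried-mass measurement of a pooled set of individuals (or a control boat)."""

    sample_id: str
    taxon_name: Optional[str]
    n_individuals: int
    raw_gain: float  # mg, dried mass minus boat tare
    split_denominator: int
    n_subsamples: int
    is_control: bool = False
    stage_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_control:
            if self.n_individuals != 0 or self.taxon_name:
                raise ValidationError("control records carry no taxon and zero individuals")
        else:
            if self.n_individuals < 1:
                raise ValidationError(
                    f"{self.sample_id}/{self.taxon_name}: non-control needs n_individuals >= 1"
                )
            if not self.taxon_name:
                raise ValidationError(f"{self.sample_id}: non-control record without taxon")
        if self.split_denominator not in VALID_SPLITS:
            raise ValidationError(
                f"{self.sample_id}: split_denominator {self.split_denominator} not in {{4, 8, 16}}"
            )
        if not 1 <= self.n_subsamples <= 100:
            raise ValidationError(
                f"{self.sample_id}: n_subsamples {self.n_subsamples} outside [1, 100] "
                "(2-ml aliquots of a 200-ml dilution)"
            )


@dataclass(frozen=True)
class LengthMeasurement:
    sample_id: str
    taxon_name: str
    length: float  # µm
    stage_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.sample_id}/{self.taxon_name}: length must be > 0")


@dataclass
class SurveyBundle:
    """A loaded survey: reference frames plus the two measurement tables.

    All members are DataFrames with the column contracts of the data
    dictionary; ``stations``/``events``/``taxa`` act as lookup tables.
    """

    stations: pd.DataFrame
    events: pd.DataFrame
    taxa: pd.DataFrame
    weighings: pd.DataFrame
    lengths: pd.DataFrame
    unknown_taxa: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.weighings["sample_id"].unique())


def normalize_taxon_name(name: str) -> str:
    """Case-insensitive match key after whitespace normalization."""
    return " ".join(str(name).split()).casefold()
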