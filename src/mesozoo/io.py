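"""Readers and writers for the delimited-text survey tables.

The survey exchange format is plain CSV (UTF-8, "." decimal); the column
contracts are in ``mesozoo/data/DATA_DICTIONARY.md``. Reference tables
(taxon conversion factors, length-weight formula registry, stations,
events) ship with the package and are integrity-checked on load.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    SchemaError,
    SurveyBundle,
    ValidationError,
    normalize_taxon_name,
)

logger = logging.getLogger(__name__)

_DATA_PKG = "mesozoo.data"

# sha256 of the packaged reference CSVs, frozen at release.
_CHECKSUMS: dict[str, str] = {
    "taxa.csv": "f9004989a8c5c22d408503b2e15a6894c31ac789a8b77fb3e58c54e37477c717",
    "formulas.csv": "f515b0782409d6255c3b6e318da48b90631fa7c286bd41bec7d45622edbc9938",
    "stations.csv": "c455cef3b01509a86f6b1adf616df67310a8ee1435d7ec6b674d869592af4c2f",
    "events.csv": "09ffe65c15345bfbeda7c9d9976310fe330e3fba05f98893e77eaf7b919d2818",
}

REQUIRED_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "stations": ("station_id", "depth", "habitat"),
    "events": ("event_id", "calendar_date"),
    "weighings": (
        "sample_id",
        "n_individuals",
        "split_denominator",
        "n_subsamples",
        "is_control",
    ),
    "lengths": ("sample_id", "taxon_name", "length"),
    "taxa": (
        "taxon_name",
        "plankton_group",
        "size_class",
        "carbon_factor",
        "energy_factor",
    ),
}


class IntegrityError(RuntimeError):
    """A packaged reference fixture does not match its recorded checksum."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files(_DATA_PKG).joinpath(name)))


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} is missing required column(s): {', '.join(missing)}")


def _read_reference(name: str) -> pd.DataFrame:
    path = _data_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _CHECKSUMS.get(name)
    if expected is not None and digest != expected:
        raise IntegrityError(f"packaged fixture {name} is corrupted (sha256 mismatch)")
    return pd.read_csv(path)


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (taxon table, length-weight formula table, station table).

    The taxon table carries the 28 conversion-factor rows; the formula
    table the 3 *Calanus* and 5 *Oithona* length-weight methods.
    """
    taxa = _read_reference("taxa.csv")
    formulas = _read_reference("formulas.csv")
    stations = _read_reference("stations.csv")
    _check_columns(taxa, "taxa")
    _check_columns(stations, "stations")
    return taxa, formulas, stations


def load_reference_events() -> pd.DataFrame:
    events = _read_reference("events.csv")
    _check_columns(events, "events")
    events = events.assign(calendar_date=pd.to_datetime(events["calendar_date"]).dt.date)
    events["day_of_year"] = [d.timetuple().tm_yday for d in events["calendar_date"]]
    return events


def _parse_numeric(df: pd.DataFrame, column: str, table: str) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        rows = list(df.index[bad][:5])
        raise ValidationError(
            f"table {table!r}, column {column!r}: non-numeric value(s) at row index {rows}"
        )
    return values


def _validate_weighings(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "taxon_name" not in df.columns:
        df["taxon_name"] = np.nan
    if "stage_tag" not in df.columns:
        df["stage_tag"] = np.nan
    # accept (tare, dried) pairs; canonical storage is the gain
    if "raw_gain" not in df.columns:
        if {"tare_mass", "dried_mass"} <= set(df.columns):
            df["raw_gain"] = _parse_numeric(df, "dried_mass", "weighings") - _parse_numeric(
                df, "tare_mass", "weighings"
            )
        else:
            raise SchemaError(
                "table 'weighings' needs either a raw_gain column or tare_mass + dried_mass"
            )
    else:
        df["raw_gain"] = _parse_numeric(df, "raw_gain", "weighings")
    df["is_control"] = df["is_control"].astype(bool)
    df["n_individuals"] = _parse_numeric(df, "n_individuals", "weighings").astype(int)
    df["split_denominator"] = _parse_numeric(df, "split_denominator", "weighings").astype(int)
    df["n_subsamples"] = _parse_numeric(df, "n_subsamples", "weighings").astype(int)

    controls = df["is_control"]
    if (df.loc[controls, "n_individuals"] != 0).any():
        raise ValidationError("control records must have n_individuals = 0")
    if (df.loc[~controls, "n_individuals"] < 1).any():
        raise ValidationError("non-control weighing with n_individuals < 1")
    bad_split = ~df["split_denominator"].isin([4, 8, 16])
    if bad_split.any():
        raise ValidationError(
            f"split_denominator outside {{4, 8, 16}} at row index {list(df.index[bad_split][:5])}"
        )
    if ((df["n_subsamples"] < 1) | (df["n_subsamples"] > 100)).any():
        raise ValidationError("n_subsamples must be in [1, 100]")
    return df


def load_survey(
    survey_dir: str | Path,
    taxa: pd.DataFrame | None = None,
) -> SurveyBundle:
    """Load and validate a survey directory of CSV tables.

    Expects ``stations.csv``, ``events.csv``, ``weighings.csv`` and
    ``lengths.csv`` under *survey_dir*. Taxon names are matched against
    the reference registry case-insensitively; unmatched names are kept
    and reported in ``bundle.unknown_taxa``.
    """
    survey_dir = Path(survey_dir)
    frames: dict[str, pd.DataFrame] = {}
    for table in ("stations", "events", "weighings", "lengths"):
        path = survey_dir / f"{table}.csv"
        if not path.exists():
            raise FileNotFoundError(f"survey table not found: {path}")
        frames[table] = pd.read_csv(path)
        _check_columns(frames[table], table)

    if taxa is None:
        taxa, _, _ = load_reference_tables()

    stations = frames["stations"].copy()
    stations["depth"] = _parse_numeric(stations, "depth", "stations")
    if (stations["depth"] <= 0).any():
        raise ValidationError("station depth must be > 0")

    events = frames["events"].copy()
    events["calendar_date"] = pd.to_datetime(events["calendar_date"]).dt.date
    events["day_of_year"] = [d.timetuple().tm_yday for d in events["calendar_date"]]

    weighings = _validate_weighings(frames["weighings"])

    lengths = frames["lengths"].copy()
    lengths["length"] = _parse_numeric(lengths, "length", "lengths")
    if (lengths["length"] <= 0).any():
        raise ValidationError("length measurements must be > 0 µm")
    if "stage_tag" not in lengths.columns:
        lengths["stage_tag"] = np.nan

    known = {normalize_taxon_name(t) for t in taxa["taxon_name"]}
    observed = set(
        weighings.loc[~weighings["is_control"], "taxon_name"].dropna()
    ) | set(lengths["taxon_name"].dropna())
    unknown = sorted(t for t in observed if normalize_taxon_name(t) not in known)
    if unknown:
        logger.warning("unknown taxa carried through with null factors: %s", unknown)

    logger.info(
        "loaded survey: %d stations, %d events, %d weighings (%d controls), %d lengths",
        len(stations),
        len(events),
        len(weighings),
        int(weighings["is_control"].sum()),
        len(lengths),
    )
    return SurveyBundle(
        stations=stations,
        events=events,
        taxa=taxa,
        weighings=weighings,
        lengths=lengths,
        unknown_taxa=unknown,
    )


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> Path:
    """Write a result table as CSV; round-trips at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if df.empty:
        logger.warning("writing empty table to %s (header only)", path)
    df.to_csv(path, index=False, float_format=float_format)
    return path


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write a named set of result tables into *out_dir*."""
    out_dir = Path(out_dir)
    return {name: write_table(df, out_dir / f"{name}.csv") for name, df in tables.items()}
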