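"""Length-weight formula registry and evaluation against measured weights.

Published length-weight relationships for *Calanus* spp. and *Oithona*
spp. are evaluated on per-sample prosome-length measurements and the
calculated mean individual dry weight is compared to the directly
measured one. Agreement within ±20 % (80-120 % of measured) counts as
satisfactory; formulas are registered in their original units and
evaluated to canonical mg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FUNCTIONAL_FORMS = ("power", "log_linear", "log_log", "power_scaled", "fixed")

_LENGTH_TO_UM = {"um": 1.0, "µm": 1.0, "mm": 1000.0}
_MASS_TO_MG = {"mg": 1.0, "ug": 1e-3, "µg": 1e-3}


@dataclass(frozen=True)
class AllometricFormula:
    """One published length→dry-weight rule.

    Functional forms (PL in ``length_unit``, DW in ``mass_unit``):

    - power:        DW = a · PL^b
    - log_linear:   log10 DW = a · PL + b
    - log_log:      log10 DW = a · log10 PL + b
    - power_scaled: DW = a · PL^b / s  (e.g. an AFDW→DW adjustment)
    - fixed:        DW = a, independent of PL

    Logarithms are base 10 throughout, the convention of the allometry
    literature these rules come from.
    """

    method_id: str
    target_taxon: str
    functional_form: str
    coef_a: float
    coef_b: Optional[float] = None
    coef_scale: Optional[float] = None
    length_unit: str = "mm"
    mass_unit: str = "mg"
    note: str = ""

    def __post_init__(self) -> None:
        if self.functional_form not in FUNCTIONAL_FORMS:
            raise ValueError(f"unknown functional form {self.functional_form!r}")
        if self.length_unit not in _LENGTH_TO_UM:
            raise ValueError(f"unknown length unit {self.length_unit!r}")
        if self.mass_unit not in _MASS_TO_MG:
            raise ValueError(f"unknown mass unit {self.mass_unit!r}")

    def evaluate(self, length_um: np.ndarray | float) -> np.ndarray | float:
        """Dry weight in mg for prosome length(s) given in µm."""
        length_um = np.asarray(length_um, dtype=float)
        if np.any(length_um <= 0):
            raise ValueError("prosome length must be > 0")
        pl = length_um / _LENGTH_TO_UM[self.length_unit]
        form = self.functional_form
        if form == "power":
            dw = self.coef_a * pl**self.coef_b
        elif form == "power_scaled":
            dw = self.coef_a * pl**self.coef_b / self.coef_scale
        elif form == "log_linear":
            dw = 10.0 ** (self.coef_a * pl + self.coef_b)
        elif form == "log_log":
            dw = 10.0 ** (self.coef_a * np.log10(pl) + self.coef_b)
        else:  # fixed
            dw = np.full_like(pl, self.coef_a)
        dw_mg = dw * _MASS_TO_MG[self.mass_unit]
        return float(dw_mg) if dw_mg.ndim == 0 else dw_mg


def registry_from_frame(formulas: pd.DataFrame) -> dict[str, AllometricFormula]:
    """Build a method_id→formula mapping from the formula registry table."""
    out: dict[str, AllometricFormula] = {}
    for row in formulas.itertuples(index=False):
        out[row.method_id] = AllometricFormula(
            method_id=row.method_id,
            target_taxon=row.target_taxon,
            functional_form=row.functional_form,
            coef_a=float(row.coef_a),
            coef_b=None if pd.isna(row.coef_b) else float(row.coef_b),
            coef_scale=None if pd.isna(row.coef_scale) else float(row.coef_scale),
            length_unit=row.length_unit,
            mass_unit=row.mass_unit,
            note=getattr(row, "note", "") or "",
        )
    return out


def default_registry() -> dict[str, AllometricFormula]:
    from .io import load_reference_tables

    _, formulas, _ = load_reference_tables()
    return registry_from_frame(formulas)


def evaluate_formula(formula: AllometricFormula, length_um: float) -> float:
    """Dry weight in mg at one prosome length (µm)."""
    return float(formula.evaluate(length_um))


def sample_calculated_mean(lengths_um: Sequence[float], formula: AllometricFormula) -> float:
    """Mean of per-individual evaluations (not the evaluation of the mean).

    The distinction matters: the power-law forms are convex in length,
    so evaluating at the mean length would underestimate the mean weight
    (Jensen's inequality).
    """
    lengths_um = np.asarray(lengths_um, dtype=float)
    if lengths_um.size == 0:
        raise ValueError("no length measurements in sample")
    return float(np.mean(formula.evaluate(lengths_um)))


def classify_band(relative_percent: float, band_fraction: float = 0.20) -> str:
    """under / satisfactory / over at closed 80 and 120 % boundaries."""
    lo, hi = 100 * (1 - band_fraction), 100 * (1 + band_fraction)
    if relative_percent < lo:
        return "under"
    if relative_percent > hi:
        return "over"
    return "satisfactory"


def compare_methods(
    lengths: pd.DataFrame,
    measured: pd.DataFrame,
    methods: Iterable[AllometricFormula],
    band_fraction: float = 0.20,
    pool_stages: bool = True,
) -> pd.DataFrame:
    """Compare calculated vs measured mean individual DW per sample.

    Parameters
    ----------
    lengths : frame with columns sample_id, taxon_name, length (µm)
        and optionally stage_tag.
    measured : frame with columns sample_id, taxon_name,
        individual_dw (mg/ind, error- and formalin-corrected,
        non-standardized).
    methods : formulas to evaluate; each is applied to the length
        measurements of its own target taxon.
    pool_stages : pool all stages of a taxon into one mean per sample
        (default); if False, compare per (sample, stage).

    Returns a tidy frame: sample_id, method_id, calculated_mean_dw,
    measured_mean_dw, relative_percent, band.
    """
    rows = []
    measured = measured.dropna(subset=["individual_dw"])
    group_cols = ["sample_id"] if pool_stages else ["sample_id", "stage_tag"]
    for formula in methods:
        taxon_lengths = lengths[lengths["taxon_name"] == formula.target_taxon]
        taxon_measured = measured[measured["taxon_name"] == formula.target_taxon]
        if pool_stages:
            measured_mean = taxon_measured.groupby("sample_id")["individual_dw"].mean()
        else:
            measured_mean = taxon_measured.groupby(group_cols)["individual_dw"].mean()
        for key, grp in taxon_lengths.groupby(group_cols[0] if pool_stages else group_cols):
            if key not in measured_mean.index:
                logger.warning(
                    "sample %s: no measured mean DW for %s, skipped", key, formula.target_taxon
                )
                continue
            calc = sample_calculated_mean(grp["length"].to_numpy(), formula)
            meas = float(measured_mean.loc[key])
            rel = 100.0 * calc / meas
            rows.append(
                {
                    "sample_id": key if pool_stages else key[0],
                    "method_id": formula.method_id,
                    "calculated_mean_dw": calc,
                    "measured_mean_dw": meas,
                    "relative_percent": rel,
                    "band": classify_band(rel, band_fraction),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "method_id",
            "calculated_mean_dw",
            "measured_mean_dw",
            "relative_percent",
            "band",
        ],
    )


def event_summary(comparisons: pd.DataFrame, sample_events: pd.Series | None = None) -> pd.DataFrame:
    """Per-event, per-method mean ± SD of relative_percent across stations.

    ``sample_events`` maps sample_id → event_id; when omitted, sample ids
    of the form ``<station>_<event>`` are parsed. SD is null for a single
    station (ddof=1).
    """
    df = comparisons.copy()
    if sample_events is not None:
        df["event_id"] = df["sample_id"].map(sample_events)
    else:
        df["event_id"] = df["sample_id"].str.split("_", n=1).str[1]
    out = (
        df.groupby(["event_id", "method_id"])["relative_percent"]
        .agg(mean_percent="mean", sd_percent=lambda s: s.std(ddof=1), n_stations="size")
        .reset_index()
    )
    return out
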