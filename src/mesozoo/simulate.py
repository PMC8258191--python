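"""Synthetic plankton surveys with known ground truth.

The generator emulates the full observation chain of a net-haul
dry-weight survey: seasonal taxon abundances at three shelf stations,
taxon-specific log-normal length distributions, power-law allometric
true weights, length-dependent capture efficiency of a 200-µm mesh,
Motoda splitting, dilution to 200 ml, 2-ml pipette subsampling,
formalin mass loss, and additive container-residue weighing error.
Every draw flows from one seed, so identical seeds give identical
surveys, and the returned truth table carries the quantities the
downstream pipeline tries to recover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import SurveyBundle

logger = logging.getLogger(__name__)

N_ALIQUOTS = 100  # 200 ml dilution / 2 ml pipette


@dataclass
class TaxonScenario:
    """Season-resolved truth for one taxon (or one stage of a taxon).

    abundance : ind/m² per event (length n_events) at the reference
        station, scaled per station by ``station_multipliers``.
    length_median_um / length_log_sd : log-normal length distribution;
        the median may vary by event (growing cohorts).
    allom_coef_mg_mm / allom_exponent : true fresh dry weight
        DW[mg] = coef · (L[mm]) ** exponent.
    weight_multiplier : optional per-event multiplier on individual
        weight at fixed length (e.g. autumn lipid build-up).
    """

    taxon_name: str
    plankton_group: str
    size_class: str
    abundance: Sequence[float]
    length_median_um: Sequence[float] | float
    length_log_sd: float
    allom_coef_mg_mm: float
    allom_exponent: float
    station_multipliers: dict[str, float] = field(default_factory=dict)
    stage_tag: Optional[str] = None
    weight_multiplier: Sequence[float] | float = 1.0

    def median_at(self, event_idx: int) -> float:
        m = self.length_median_um
        return float(m[event_idx]) if np.ndim(m) else float(m)

    def weight_mult_at(self, event_idx: int) -> float:
        m = self.weight_multiplier
        return float(m[event_idx]) if np.ndim(m) else float(m)

    def fresh_dw_mg(self, lengths_um: np.ndarray, event_idx: int) -> np.ndarray:
        return (
            self.allom_coef_mg_mm
            * (lengths_um / 1000.0) ** self.allom_exponent
            * self.weight_mult_at(event_idx)
        )


@dataclass
class SimulationConfig:
    """Study design plus observation model for one synthetic survey."""

    stations: list[tuple[str, float]]  # (station_id, depth m)
    events: list[tuple[str, str]]  # (event_id, ISO date)
    taxa: list[TaxonScenario]
    formalin_loss: float = 0.40
    control_error_mean: float = 0.016  # mg
    control_error_sd: float = 0.01075  # mg
    n_controls: int = 3
    net_area: float = 0.25  # m²
    capture_l50_um: float = 550.0
    capture_scale_um: float = 65.0
    ideal_capture: bool = False
    split_thresholds: tuple[int, int] = (4000, 8000)  # counts for split 8 / 16
    subsample_target: int = 100  # individuals to pool per weighing
    max_lengths_per_taxon: int = 400
    overdispersion: Optional[float] = None  # negative-binomial k; None = Poisson

    def __post_init__(self) -> None:
        if not 0 <= self.formalin_loss < 1:
            raise ValueError("formalin_loss must be in [0, 1)")
        for t in self.taxa:
            if np.any(np.asarray(t.abundance) < 0):
                raise ValueError(f"{t.taxon_name}: abundances must be >= 0")
            if len(t.abundance) != len(self.events):
                raise ValueError(f"{t.taxon_name}: abundance length != number of events")


def capture_probability(length_um: np.ndarray | float, config: SimulationConfig) -> np.ndarray | float:
    """Probability that an individual of given length is retained by the net.

    A logistic curve in length emulating the under-catch of a 200-µm
    mesh: roughly 0.1 at 400 µm, near 1 from 1000 µm upward, monotone
    nondecreasing. With ``ideal_capture`` the curve is identically 1.
    """
    length_um = np.asarray(length_um, dtype=float)
    if np.any(length_um < 0):
        raise ValueError("length must be nonnegative")
    if config.ideal_capture:
        p = np.ones_like(length_um)
    else:
        p = 1.0 / (1.0 + np.exp(-(length_um - config.capture_l50_um) / config.capture_scale_um))
    return float(p) if p.ndim == 0 else p


def choose_split(total_individuals: int, config: SimulationConfig) -> int:
    """Motoda split denominator from haul density (dense hauls split finer)."""
    lo, hi = config.split_thresholds
    if total_individuals >= hi:
        return 16
    if total_individuals >= lo:
        return 8
    return 4


def default_scenario() -> SimulationConfig:
    """The packaged study design: 3 stations × 8 events, 16 scenario rows.

    Emulates a sub-Arctic shelf year: a *Calanus*-like copepod dominating
    annual biomass (deepest station richest), a pteropod peaking in
    autumn, cirripede nauplii peaking April–May with a growing length
    cohort (median 392 → 703 µm), amphinomid larvae confined to the July
    event, and a backdrop of small copepods and meroplankton. Abundances
    are scenario choices on the order of net-haul observations, not
    measured values.
    """
    stations = [("C", 40.0), ("B", 80.0), ("T", 215.0)]
    events = [
        ("E1", "2013-09-17"),
        ("E2", "2013-10-23"),
        ("E3", "2014-01-22"),
        ("E4", "2014-04-01"),
        ("E5", "2014-05-01"),
        ("E6", "2014-06-10"),
        ("E7", "2014-07-22"),
        ("E8", "2014-08-20"),
    ]
    taxa = [
        TaxonScenario(
            "Calanus spp.", "holoplankton", "LMZ",
            abundance=[800, 400, 150, 700, 8000, 12000, 9000, 3000],
            length_median_um=2500, length_log_sd=0.20,
            allom_coef_mg_mm=0.006458, allom_exponent=3.9,
            station_multipliers={"C": 0.5, "B": 1.5, "T": 4.0},
            stage_tag="copepodite",
        ),
        TaxonScenario(
            "Calanus spp.", "holoplankton", "LMZ",
            abundance=[0, 0, 0, 400, 3000, 1500, 300, 100],
            length_median_um=520, length_log_sd=0.12,
            allom_coef_mg_mm=0.006458, allom_exponent=3.9,
            station_multipliers={"C": 1.0, "B": 2.0, "T": 3.0},
            stage_tag="nauplius",
        ),
        TaxonScenario(
            "Oithona spp.", "holoplankton", "SMZ",
            abundance=[4000, 3000, 1500, 2500, 6000, 8000, 7000, 5000],
            length_median_um=520, length_log_sd=0.15,
            allom_coef_mg_mm=0.0289, allom_exponent=3.643,
        ),
        TaxonScenario(
            "Limacina retroversa", "holoplankton", "LMZ",
            abundance=[3000, 6000, 0, 0, 0, 0, 300, 1200],
            length_median_um=800, length_log_sd=0.45,
            allom_coef_mg_mm=0.09, allom_exponent=3.0,
            station_multipliers={"C": 2.0, "B": 2.0, "T": 0.5},
        ),
        TaxonScenario(
            "Metridia longa", "holoplankton", "LMZ",
            abundance=[300, 450, 900, 450, 300, 200, 200, 300],
            length_median_um=1600, length_log_sd=0.18,
            allom_coef_mg_mm=0.0075, allom_exponent=3.4,
            station_multipliers={"C": 1.5, "B": 1.0, "T": 1.5},
        ),
        TaxonScenario(
            "Clausocalanidae", "holoplankton", "SMZ",
            abundance=[2500, 1500, 600, 3000, 6000, 5000, 4000, 3000],
            length_median_um=750, length_log_sd=0.15,
            allom_coef_mg_mm=0.02, allom_exponent=3.2,
        ),
        TaxonScenario(
            "Copepoda nauplii", "holoplankton", "SMZ",
            abundance=[400, 300, 150, 5000, 30000, 9000, 2000, 600],
            length_median_um=500, length_log_sd=0.10,
            allom_coef_mg_mm=0.025, allom_exponent=3.0,
        ),
        TaxonScenario(
            "Cirripedia", "meroplankton", "SMZ",
            abundance=[0, 0, 0, 4000, 3600, 600, 100, 0],
            length_median_um=[400, 400, 400, 392, 703, 720, 700, 700],
            length_log_sd=0.18,
            allom_coef_mg_mm=0.04, allom_exponent=3.1,
            station_multipliers={"C": 2.0, "B": 1.5, "T": 0.5},
        ),
        TaxonScenario(
            "Centropages typicus", "holoplankton", "SMZ",
            abundance=[4000, 500, 0, 0, 0, 0, 0, 400],
            length_median_um=850, length_log_sd=0.15,
            allom_coef_mg_mm=0.02, allom_exponent=3.2,
        ),
        TaxonScenario(
            "Temora longicornis", "holoplankton", "SMZ",
            abundance=[3200, 400, 0, 0, 0, 0, 0, 300],
            length_median_um=780, length_log_sd=0.15,
            allom_coef_mg_mm=0.022, allom_exponent=3.2,
        ),
        TaxonScenario(
            "Fritillaria borealis", "holoplankton", "SMZ",
            abundance=[800, 500, 150, 2500, 1800, 800, 500, 600],
            length_median_um=450, length_log_sd=0.20,
            allom_coef_mg_mm=0.008, allom_exponent=2.8,
        ),
        TaxonScenario(
            "Bivalvia", "meroplankton", "SMZ",
            abundance=[400, 200, 0, 500, 1400, 2200, 1600, 700],
            length_median_um=330, length_log_sd=0.12,
            allom_coef_mg_mm=0.03, allom_exponent=3.0,
            station_multipliers={"C": 1.5, "B": 1.2, "T": 0.6},
        ),
        TaxonScenario(
            "Gastropoda", "meroplankton", "SMZ",
            abundance=[500, 350, 0, 350, 1100, 1600, 1800, 900],
            length_median_um=350, length_log_sd=0.15,
            allom_coef_mg_mm=0.035, allom_exponent=3.0,
            station_multipliers={"C": 1.5, "B": 1.2, "T": 0.6},
        ),
        TaxonScenario(
            "Bryozoa", "meroplankton", "SMZ",
            abundance=[150, 80, 0, 700, 1000, 500, 350, 150],
            length_median_um=420, length_log_sd=0.12,
            allom_coef_mg_mm=0.02, allom_exponent=2.9,
            station_multipliers={"C": 1.8, "B": 1.2, "T": 0.4},
        ),
        TaxonScenario(
            "Amphinomidae", "meroplankton", "SMZ",
            abundance=[0, 0, 0, 0, 0, 0, 6000, 0],
            length_median_um=900, length_log_sd=0.20,
            allom_coef_mg_mm=0.05, allom_exponent=3.0,
            station_multipliers={"C": 2.0, "B": 1.5, "T": 0.3},
        ),
        TaxonScenario(
            "Fish eggs", "ichthyoplankton", "LMZ",
            abundance=[0, 0, 0, 900, 1100, 0, 0, 0],
            length_median_um=1250, length_log_sd=0.05,
            allom_coef_mg_mm=0.03, allom_exponent=3.0,
        ),
        TaxonScenario(
            "Cod larvae", "ichthyoplankton", "LMZ",
            abundance=[0, 0, 0, 300, 650, 120, 0, 0],
            length_median_um=4200, length_log_sd=0.12,
            allom_coef_mg_mm=0.004, allom_exponent=3.0,
        ),
    ]
    return SimulationConfig(stations=stations, events=events, taxa=taxa)


def _draw_count(rng: np.random.Generator, lam: float, overdispersion: Optional[float]) -> int:
    if lam <= 0:
        return 0
    if overdispersion is None:
        return int(rng.poisson(lam))
    k = overdispersion  # gamma-Poisson mixture with shape k
    return int(rng.poisson(rng.gamma(k, lam / k)))


def simulate_survey(
    config: SimulationConfig, seed: int
) -> tuple[SurveyBundle, pd.DataFrame]:
    """Draw one survey and its truth table.

    Per sample (station × event) and scenario row: the haul count is
    Poisson (optionally gamma-mixed) around areal abundance × net area;
    individual lengths are log-normal; capture is Bernoulli-thinned by
    the logistic mesh-retention curve; one Motoda part (chosen by haul
    density) is retained by binomial thinning; the part's individuals
    are spread over the 100 possible 2-ml aliquots and aliquots are
    pooled per taxon until the target count is reached. The weighing
    record is the summed formalin-reduced dry weight of the pooled
    individuals plus one additive Normal error draw; three pure-error
    control records accompany every sample.

    Truth rows carry the water-column quantities before any observation
    effect: areal fresh biomass, areal abundance, mean individual DW.
    """
    if seed is None:
        raise ValueError("a seed is required; surveys must be reproducible")
    rng = np.random.default_rng(seed)
    from .io import load_reference_tables

    taxa_ref, _, _ = load_reference_tables()

    stations = pd.DataFrame(
        [(s, d, {"C": "coast", "B": "bank", "T": "trough"}.get(s, "coast")) for s, d in config.stations],
        columns=["station_id", "depth", "habitat"],
    )
    events = pd.DataFrame(config.events, columns=["event_id", "calendar_date"])
    events["calendar_date"] = pd.to_datetime(events["calendar_date"]).dt.date
    events["day_of_year"] = [d.timetuple().tm_yday for d in events["calendar_date"]]

    weighing_rows: list[dict] = []
    length_rows: list[dict] = []
    truth_rows: list[dict] = []

    for ev_idx, ev in events.iterrows():
        for station_id, _depth in config.stations:
            sample_id = f"{station_id}_{ev['event_id']}"
            # --- draw the haul -------------------------------------------------
            haul: list[tuple[TaxonScenario, np.ndarray, np.ndarray]] = []
            for scen in config.taxa:
                mult = scen.station_multipliers.get(station_id, 1.0)
                abundance = scen.abundance[ev_idx] * mult  # ind/m²
                n_raw = _draw_count(rng, abundance * config.net_area, config.overdispersion)
                lengths = rng.lognormal(
                    mean=np.log(scen.median_at(ev_idx)), sigma=scen.length_log_sd, size=n_raw
                )
                fresh = scen.fresh_dw_mg(lengths, ev_idx)
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "station_id": station_id,
                        "event_id": ev["event_id"],
                        "taxon_name": scen.taxon_name,
                        "stage_tag": scen.stage_tag,
                        "true_abundance": n_raw / config.net_area,
                        "true_areal_biomass": float(fresh.sum()) / config.net_area,
                        "true_mean_individual_dw": float(fresh.mean()) if n_raw else np.nan,
                    }
                )
                keep = rng.random(n_raw) < capture_probability(lengths, config)
                haul.append((scen, lengths[keep], fresh[keep]))

            total_captured = sum(len(lengths) for _, lengths, _ in haul)
            split = choose_split(total_captured, config)

            # --- split, dilute, subsample, weigh ------------------------------
            for scen, lengths, fresh in haul:
                in_part = rng.random(len(lengths)) < 1.0 / split
                lengths_p, fresh_p = lengths[in_part], fresh[in_part]
                if len(lengths_p) == 0:
                    continue
                aliquot = rng.integers(0, N_ALIQUOTS, size=len(lengths_p))
                order = np.argsort(aliquot, kind="stable")
                counts = np.bincount(aliquot, minlength=N_ALIQUOTS)
                cum = np.cumsum(counts)
                # pool aliquots in pipetting order until the target is reached
                used = int(np.searchsorted(cum, min(config.subsample_target, cum[-1]))) + 1
                pooled = order[: cum[used - 1]]
                if len(pooled) == 0:
                    continue
                formalin_mass = fresh_p[pooled].sum() * (1.0 - config.formalin_loss)
                gain = formalin_mass + rng.normal(config.control_error_mean, config.control_error_sd)
                weighing_rows.append(
                    {
                        "sample_id": sample_id,
                        "taxon_name": scen.taxon_name,
                        "stage_tag": scen.stage_tag,
                        "n_individuals": int(len(pooled)),
                        "raw_gain": float(gain),
                        "split_denominator": split,
                        "n_subsamples": used,
                        "is_control": False,
                        # truth-side convenience: the error-free pooled mass
                        "true_pooled_mass": float(formalin_mass),
                    }
                )
                for length in lengths_p[pooled][: config.max_lengths_per_taxon]:
                    length_rows.append(
                        {
                            "sample_id": sample_id,
                            "taxon_name": scen.taxon_name,
                            "length": float(length),
                            "stage_tag": scen.stage_tag,
                        }
                    )

            for _ in range(config.n_controls):
                weighing_rows.append(
                    {
                        "sample_id": sample_id,
                        "taxon_name": None,
                        "stage_tag": None,
                        "n_individuals": 0,
                        "raw_gain": float(
                            rng.normal(config.control_error_mean, config.control_error_sd)
                        ),
                        "split_denominator": split,
                        "n_subsamples": 1,
                        "is_control": True,
                        "true_pooled_mass": 0.0,
                    }
                )

    weighings = pd.DataFrame(weighing_rows)
    lengths = pd.DataFrame(length_rows, columns=["sample_id", "taxon_name", "length", "stage_tag"])
    truth = pd.DataFrame(truth_rows)
    bundle = SurveyBundle(
        stations=stations, events=events, taxa=taxa_ref, weighings=weighings, lengths=lengths
    )
    logger.info(
        "simulated survey (seed %d): %d weighings, %d lengths", seed, len(weighings), len(lengths)
    )
    return bundle, truth


def write_survey(bundle: SurveyBundle, truth: pd.DataFrame, out_dir: str | Path,
                 config: SimulationConfig | None = None) -> None:
    """Write the survey CSVs plus truth and, for provenance, the config."""
    from .io import write_table

    out_dir = Path(out_dir)
    write_table(bundle.stations, out_dir / "stations.csv")
    write_table(bundle.events, out_dir / "events.csv")
    write_table(bundle.weighings, out_dir / "weighings.csv")
    write_table(bundle.lengths, out_dir / "lengths.csv")
    write_table(truth, out_dir / "truth.csv")
    if config is not None:
        payload = asdict(config)
        for t in payload["taxa"]:
            for key, val in t.items():
                if isinstance(val, np.ndarray):
                    t[key] = val.tolist()
        (out_dir / "scenario.json").write_text(json.dumps(payload, indent=2, default=list))
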