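# Data dictionary

All tables are UTF-8 CSV with "." as decimal separator. Masses are in mg,
lengths in µm, areal quantities per m² of sea surface.

## Survey input tables

### stations.csv
| column | type | meaning |
|---|---|---|
| station_id | str | short station label (e.g. C, B, T) |
| depth | float > 0 | bottom depth, m |
| habitat | str | one of coast, bank, trough |

### events.csv
| column | type | meaning |
|---|---|---|
| event_id | str | sampling-event label |
| calendar_date | ISO date | sampling date; day-of-year is derived from it |

The packaged event dates E1 (September), E6 (June) and E8 (August) are
plausible placeholders for dates not printed in the source tables; the
others are the printed sampling dates.

### weighings.csv
One row per dried-and-weighed pool of individuals (or per control boat).

| column | type | meaning |
|---|---|---|
| sample_id | str | `<station_id>_<event_id>` |
| taxon_name | str | empty for control boats |
| stage_tag | str | optional stage (e.g. nauplius / copepodite for *Calanus*) |
| n_individuals | int ≥ 0 | individuals pooled into the boat; 0 for controls |
| raw_gain | float | dried mass minus boat tare, mg (may also be given as `tare_mass` + `dried_mass`) |
| split_denominator | int ∈ {4, 8, 16} | Motoda split fraction used |
| n_subsamples | int ≥ 1 | number of 2-ml pipette subsamples pooled |
| is_control | bool | True for distilled-water control boats |

### lengths.csv
| column | type | meaning |
|---|---|---|
| sample_id | str | as above |
| taxon_name | str | taxon of the measured individual |
| length | float > 0 | µm; prosome length for copepods, longest body extension otherwise |
| stage_tag | str | optional stage |

## Packaged reference tables

### taxa.csv
The 28-taxon conversion-factor registry: carbon_factor in mg C per mg DW,
energy_factor in J per mg DW, size_class SMZ/LMZ, cross_class_flag marks
the two taxa spanning both size classes that are analysed as LMZ.

### formulas.csv
Length–weight formula registry. functional_form is one of power
(DW = a·PLᵇ), log_linear (log₁₀DW = a·PL + b), log_log
(log₁₀DW = a·log₁₀PL + b), power_scaled (DW = a·PLᵇ/s), fixed (DW = a).
length_unit/mass_unit give the units of the original formula; evaluation
always returns canonical mg.

## Output tables

### biomass.csv
Per weighing record: corrected_mass (mg, error-subtracted and
formalin-corrected, not standardized), reliable flag, areal_biomass
(mg DW/m²), individual_dw (mg/ind), carbon (mg C/m²), energy (J/m²),
plankton_group, size_class. Unreliable records keep NaN in the derived
columns but are never dropped.

### method_comparison.csv
sample_id, method_id, calculated_mean_dw (mg), measured_mean_dw (mg),
relative_percent (100 × calculated / measured), band (under / satisfactory /
over at the 80–120 % boundaries, closed).
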