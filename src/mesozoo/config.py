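"""Numeric constants of the weighing/standardization protocol.

Every constant of the laboratory chain lives here so that the pipeline
has a single source of truth and alternative protocols are one config
file away.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Protocol constants.

    mean_control_error : mg, average weight gain of distilled-water
        control boats; subtracted from every measurement.
    reliability_sd : mg, standard deviation of the control gains; the
        reliability threshold is ``sd_multiplier * reliability_sd``
        (0.043 mg at the defaults).
    formalin_loss : fraction of dry mass lost to formaldehyde
        preservation; corrected by dividing by (1 - loss), i.e. the
        familiar x1.67 factor at 40 % loss.
    net_area : m², mouth opening of the WP2 net.
    dilution_ml / pipette_ml : the split part is diluted to 200 ml and
        subsampled with a 2-ml fixed-volume pipette.
    smz_threshold_um : size-class boundary (µm) between small and large
        mesozooplankton.
    band_fraction : half-width of the "satisfactory" band when comparing
        calculated to measured individual dry weight (0.2 -> 80-120 %).
    threshold_on_corrected : apply the reliability threshold to the
        error-corrected gain (the protocol order: subtract, then filter);
        set False to threshold the raw gain instead.
    """

    mean_control_error: float = 0.016
    reliability_sd: float = 0.01075
    sd_multiplier: float = 4.0
    formalin_loss: float = 0.40
    net_area: float = 0.25
    dilution_ml: float = 200.0
    pipette_ml: float = 2.0
    smz_threshold_um: float = 1000.0
    band_fraction: float = 0.20
    threshold_on_corrected: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.formalin_loss < 1:
            raise ValueError("formalin_loss must be in [0, 1)")
        if self.net_area <= 0 or self.dilution_ml <= 0 or self.pipette_ml <= 0:
            raise ValueError("net_area, dilution_ml and pipette_ml must be positive")

    @property
    def reliability_threshold(self) -> float:
        """mg; gains at or below this are discarded as unreliable."""
        return self.sd_multiplier * self.reliability_sd

    @property
    def formalin_multiplier(self) -> float:
        return 1.0 / (1.0 - self.formalin_loss)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
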