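"""Early fluid-overload percentage.

FO% = (total fluid in [L] − total fluid out [L]) / admission weight [kg] × 100,
accumulated over a window starting at admission (default the first 24 h).
FO+ means FO% strictly greater than 10; a balance of exactly 10.000% is FO−.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import PatientRecord, Series

logger = logging.getLogger(__name__)

FO_POSITIVE_THRESHOLD = 10.0


@dataclass(frozen=True)
class FluidSummary:
    patient_id: str
    fo_percent: float
    fo_positive: bool

    def __post_init__(self) -> None:
        if self.fo_positive != (self.fo_percent > FO_POSITIVE_THRESHOLD):
            raise ValueError("fo_positive must hold exactly when fo_percent > 10")


def fo_percent(
    fluid_in_series: Series,
    fluid_out_series: Series,
    admission_weight_kg: float,
    window_end_h: float = 24.0,
    patient_id: str = "",
) -> FluidSummary:
    """Net fluid balance as a percentage of admission body weight.

    Volumes are recorded in mL and summed over [0, window_end_h] before the
    conversion to litres.  Empty series count as zero intake/output.
    """
    if admission_weight_kg <= 0:
        raise ValueError("admission weight must be positive")
    fin = fluid_in_series.clip(window_end_h)
    fout = fluid_out_series.clip(window_end_h)
    if len(fin) == 0 and len(fout) == 0:
        logger.warning("patient %s: no fluid recordings in window; FO%% = 0", patient_id)
    net_l = (fin.values.sum() - fout.values.sum()) / 1000.0
    fo = net_l / admission_weight_kg * 100.0
    return FluidSummary(patient_id, float(fo), bool(fo > FO_POSITIVE_THRESHOLD))


def summarize_fluid(record: PatientRecord, window_end_h: float = 24.0) -> FluidSummary:
    """FO summary for one patient record."""
    return fo_percent(
        record.fluid_in_series,
        record.fluid_out_series,
        record.admission_weight_kg,
        window_end_h,
        record.patient_id,
    )
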