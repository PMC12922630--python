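"""Constants for the Tmax/VPDmax -> heat index -> indoor WBGT chain.

All coefficients live in one machine-readable table
(``data/heat_index_constants.json``) so the whole transform is auditable
against independent transcriptions of the published algorithms. This module
just loads that table once and exposes it as plain Python objects.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = [
    "CONSTANTS",
    "MAGNUS",
    "NWS_SIMPLE",
    "ROTHFUSZ",
    "LOW_RH_ADJ",
    "HIGH_RH_ADJ",
    "WBGT_QUADRATIC",
    "NIOSH_THRESHOLD_C",
]


def _load() -> dict:
    with resources.files("hazardheat.data").joinpath(
        "heat_index_constants.json"
    ).open("r") as fh:
        return json.load(fh)


CONSTANTS: dict = _load()

#: Magnus saturation-vapour-pressure coefficients (over water), hPa / degC.
MAGNUS: dict = CONSTANTS["magnus"]

#: Simple Steadman-derived branch of the NWS heat-index procedure (degF).
NWS_SIMPLE: dict = CONSTANTS["nws_simple"]

#: Rothfusz 9-coefficient regression (degF).
ROTHFUSZ: dict = CONSTANTS["rothfusz"]

#: Low-humidity subtraction applied for RH < 13 %, 80-112 degF.
LOW_RH_ADJ: dict = CONSTANTS["low_rh_adjustment"]

#: High-humidity addition applied for RH > 85 %, 80-87 degF.
HIGH_RH_ADJ: dict = CONSTANTS["high_rh_adjustment"]

#: Default indoor HI(degF) -> WBGT(degC) quadratic (0.5 m/s wind, no radiant load).
WBGT_QUADRATIC: dict = CONSTANTS["wbgt_quadratic"]

#: NIOSH recommended limit for acclimatised workers at moderate workloads, degC.
NIOSH_THRESHOLD_C: float = 28.0
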