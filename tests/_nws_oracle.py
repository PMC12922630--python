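"""Independent scalar transcription of the NWS heat-index procedure.

Written directly from the published algorithm description, separately from
the package implementation, to serve as the oracle in equivalence tests.
Works entirely in degF; callers convert.
"""

import math


def nws_heat_index_f(t_f: float, rh: float) -> float:
    """Heat index in degF for air temperature t_f (degF) and RH (%)."""
    simple = 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094)
    if simple < 80.0:
        return simple
    hi = (
        -42.379
        + 2.04901523 * t_f
        + 10.14333127 * rh
        - 0.22475541 * t_f * rh
        - 6.83783e-3 * t_f * t_f
        - 5.481717e-2 * rh * rh
        + 1.22874e-3 * t_f * t_f * rh
        + 8.5282e-4 * t_f * rh * rh
        - 1.99e-6 * t_f * t_f * rh * rh
    )
    if rh < 13.0 and 80.0 <= t_f <= 112.0:
        hi -= ((13.0 - rh) / 4.0) * math.sqrt((17.0 - abs(t_f - 95.0)) / 17.0)
    elif rh > 85.0 and 80.0 <= t_f <= 87.0:
        hi += ((rh - 85.0) / 10.0) * ((87.0 - t_f) / 5.0)
    return hi


def magnus_es_hpa(t_c: float) -> float:
    """Magnus saturation vapour pressure, independent evaluation."""
    return 6.112 * math.exp(17.67 * t_c / (t_c + 243.5))
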