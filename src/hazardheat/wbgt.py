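"""Daily (Tmax, VPDmax) -> relative humidity -> heat index -> indoor WBGT.

The chain recovers relative humidity from vapour pressure deficit via a
Magnus saturation-vapour-pressure curve, applies the US National Weather
Service heat-index procedure (simple Steadman-derived branch, switching to
the full Rothfusz regression with both documented humidity-range
adjustments when the simple branch reaches 80 degF), and maps the heat
index onto indoor/shaded wet-bulb globe temperature with a quadratic that
assumes a fixed 0.5 m/s wind and no radiant load.

Public interfaces take and return degC and hPa; degF exists only inside
:func:`heat_index` and :func:`wbgt_from_heat_index`. NaN is the explicit
missing-data marker and propagates through every operation; infinities and
physically impossible values raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    HIGH_RH_ADJ,
    LOW_RH_ADJ,
    MAGNUS,
    NWS_SIMPLE,
    ROTHFUSZ,
    WBGT_QUADRATIC,
)

__all__ = [
    "TEMP_RANGE_C",
    "WbgtTransformParams",
    "saturation_vapor_pressure",
    "relative_humidity_from_vpd",
    "heat_index",
    "wbgt_from_heat_index",
    "daily_wbgt_series",
]

#: Physical plausibility range for 2 m air temperature, degC.
TEMP_RANGE_C = (-60.0, 60.0)


def _c_to_f(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def _f_to_c(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def _check_finite(x, name: str) -> np.ndarray:
    """Coerce to float array; allow NaN (missing), reject +-inf."""
    arr = np.asarray(x, dtype=float)
    if np.isinf(arr).any():
        raise ValueError(f"{name} contains non-finite (infinite) values")
    return arr


@dataclass(frozen=True)
class WbgtTransformParams:
    """Quadratic HI(degF) -> WBGT(degC) transform parameters.

    WBGT = quad_a * HI_F**2 + quad_b * HI_F + quad_c.  The transform must be
    strictly increasing over ``valid_hi_range`` (degF); construction fails
    otherwise.  The defaults are the indoor (0.5 m/s wind, no radiant load)
    quadratic of the Bernard occupational-heat lineage.
    """

    quad_a: float = WBGT_QUADRATIC["a"]
    quad_b: float = WBGT_QUADRATIC["b"]
    quad_c: float = WBGT_QUADRATIC["c"]
    valid_hi_range: tuple[float, float] = field(
        default=tuple(WBGT_QUADRATIC["valid_hi_range_f"])
    )

    def __post_init__(self):
        lo, hi = self.valid_hi_range
        if not lo < hi:
            raise ValueError("valid_hi_range must be an increasing interval")
        # derivative 2a*x + b is linear: checking the endpoints covers the range
        if 2 * self.quad_a * lo + self.quad_b <= 0 or (
            2 * self.quad_a * hi + self.quad_b <= 0
        ):
            raise ValueError(
                "quadratic transform is not strictly increasing over "
                f"valid_hi_range {self.valid_hi_range}"
            )

    def wbgt_c(self, hi_f):
        hi_f = np.asarray(hi_f, dtype=float)
        return self.quad_a * hi_f**2 + self.quad_b * hi_f + self.quad_c

    def hi_f_at_wbgt(self, wbgt_c: float) -> float:
        """Heat index (degF) at which the transform crosses ``wbgt_c``.

        Solves the quadratic on the increasing branch; with quad_a == 0 the
        transform is linear and the root is exact.
        """
        a, b, c = self.quad_a, self.quad_b, self.quad_c - wbgt_c
        if a == 0:
            return -c / b
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError(f"transform never reaches WBGT={wbgt_c} degC")
        # increasing branch root: for a<0 it is the smaller (-b + sqrt)/2a
        return (-b + np.sqrt(disc)) / (2 * a)


def saturation_vapor_pressure(t):
    """Saturation vapour pressure over water, hPa, Magnus form.

    e_s(t) = 6.112 * exp(17.67 * t / (t + 243.5)) with t in degC.
    Strictly positive and strictly increasing on the physical range.
    """
    t = _check_finite(t, "temperature")
    with np.errstate(invalid="ignore"):
        # NaN (missing) compares False on both sides, so it passes through
        bad = (t < TEMP_RANGE_C[0]) | (t > TEMP_RANGE_C[1])
    if np.any(bad):
        raise ValueError(
            f"temperature outside physical range {TEMP_RANGE_C} degC"
        )
    es = MAGNUS["a"] * np.exp(MAGNUS["b"] * t / (t + MAGNUS["c"]))
    return es if es.ndim else float(es)


def relative_humidity_from_vpd(t_max, vpd_max):
    """Relative humidity (%) recovered from Tmax (degC) and VPDmax (hPa).

    RH = 100 * (1 - VPD / e_s(Tmax)), clamped to [0, 100].  VPD larger than
    the saturation pressure (possible with mismatched formulations) clamps
    to 0 rather than going negative.
    """
    vpd = _check_finite(vpd_max, "vpd_max")
    if np.nanmin(vpd, initial=0.0) < 0:
        raise ValueError("vpd_max must be non-negative")
    es = saturation_vapor_pressure(t_max)
    rh = 100.0 * (1.0 - vpd / np.asarray(es, dtype=float))
    rh = np.clip(rh, 0.0, 100.0)
    return rh if rh.ndim else float(rh)


def heat_index(t_max, rh):
    """NWS heat index, degC in / degC out.

    Computes the simple Steadman-derived branch in degF; wherever that
    branch reaches 80 degF, replaces it with the full Rothfusz regression
    plus the documented low-humidity (RH < 13 %, 80-112 degF) subtraction
    and high-humidity (RH > 85 %, 80-87 degF) addition.
    """
    t_c = _check_finite(t_max, "t_max")
    rh = _check_finite(rh, "rh")
    t_c, rh = np.broadcast_arrays(t_c, rh)
    scalar = t_c.ndim == 0
    t_c, rh = np.atleast_1d(t_c), np.atleast_1d(rh)
    with np.errstate(invalid="ignore"):
        if np.any((rh < 0) | (rh > 100)):
            raise ValueError("rh must lie in [0, 100] percent")
        lo, hi = TEMP_RANGE_C
        if np.any((t_c < lo) | (t_c > hi)):
            raise ValueError(f"t_max outside physical range {TEMP_RANGE_C} degC")

    t = _c_to_f(t_c)
    c61, c68, c12, c094, half = NWS_SIMPLE["coeffs"]
    hi_f = half * (t + c61 + (t - c68) * c12 + rh * c094)

    with np.errstate(invalid="ignore"):
        full = hi_f >= NWS_SIMPLE["rothfusz_switch_f"]
    if full.any():
        c = ROTHFUSZ["coeffs"]
        tf, rf = t[full], rh[full]
        reg = (
            c[0]
            + c[1] * tf
            + c[2] * rf
            + c[3] * tf * rf
            + c[4] * tf * tf
            + c[5] * rf * rf
            + c[6] * tf * tf * rf
            + c[7] * tf * rf * rf
            + c[8] * tf * tf * rf * rf
        )
        lo_t, hi_t = LOW_RH_ADJ["t_range_f"]
        low = (rf < LOW_RH_ADJ["rh_max"]) & (tf >= lo_t) & (tf <= hi_t)
        reg = np.where(
            low,
            reg
            - ((LOW_RH_ADJ["rh_max"] - rf) / 4.0)
            * np.sqrt(np.clip((17.0 - np.abs(tf - 95.0)) / 17.0, 0.0, None)),
            reg,
        )
        lo_t, hi_t = HIGH_RH_ADJ["t_range_f"]
        high = (rf > HIGH_RH_ADJ["rh_min"]) & (tf >= lo_t) & (tf <= hi_t)
        reg = np.where(
            high,
            reg + ((rf - HIGH_RH_ADJ["rh_min"]) / 10.0) * ((hi_t - tf) / 5.0),
            reg,
        )
        hi_f = hi_f.copy()
        hi_f[full] = reg

    out = _f_to_c(hi_f)
    return float(out[0]) if scalar else out


def wbgt_from_heat_index(hi, params: WbgtTransformParams | None = None):
    """Indoor/shaded WBGT (degC) from heat index (degC) via the quadratic.

    Warns (does not fail) when the heat index falls outside the range over
    which the transform is trusted.
    """
    if params is None:
        params = WbgtTransformParams()
    hi_c = _check_finite(hi, "heat index")
    hi_f = _c_to_f(hi_c)
    with np.errstate(invalid="ignore"):
        lo, hi_lim = params.valid_hi_range
        outside = (hi_f < lo) | (hi_f > hi_lim)
    if np.any(outside):
        warnings.warn(
            "heat index outside the trusted range "
            f"[{lo}, {hi_lim}] degF of the WBGT transform",
            RuntimeWarning,
            stacklevel=2,
        )
    out = params.wbgt_c(hi_f)
    return out if out.ndim else float(out)


def daily_wbgt_series(
    dates,
    t_max,
    vpd_max,
    params: WbgtTransformParams | None = None,
) -> pd.DataFrame:
    """Element-wise WBGT chain over a daily series.

    Parameters
    ----------
    dates
        Unique, sorted calendar dates (anything ``pd.DatetimeIndex`` accepts).
    t_max, vpd_max
        Daily maxima, degC and hPa. NaN marks a missing day and propagates.
    params
        WBGT transform parameters; defaults to the shipped quadratic.

    Returns
    -------
    DataFrame with columns ``date``, ``t_max``, ``vpd_max``, ``hi_max``,
    ``wbgt_max``; length equals the input length (missing days are never
    dropped).
    """
    idx = pd.DatetimeIndex(dates)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique()
        raise ValueError(f"duplicate dates in series: {list(dupes[:3])}")
    if not idx.is_monotonic_increasing:
        raise ValueError("dates must be sorted ascending")
    t = np.asarray(t_max, dtype=float)
    v = np.asarray(vpd_max, dtype=float)
    if not (len(idx) == len(t) == len(v)):
        raise ValueError("dates, t_max and vpd_max must have equal length")

    rh = relative_humidity_from_vpd(t, v) if len(t) else np.array([])
    hi = heat_index(t, rh) if len(t) else np.array([])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        wbgt = wbgt_from_heat_index(hi, params) if len(t) else np.array([])
    return pd.DataFrame(
        {
            "date": idx,
            "t_max": t,
            "vpd_max": v,
            "hi_max": np.asarray(hi, dtype=float),
            "wbgt_max": np.asarray(wbgt, dtype=float),
        }
    )
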