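{
  "description": "Machine-readable constants for the WBGT transform chain: Magnus saturation vapour pressure, the NWS heat-index procedure (simple Steadman branch + Rothfusz regression + humidity-range adjustments), and the default indoor HI->WBGT quadratic.",
  "magnus": {
    "comment": "e_s(t) = a * exp(b * t / (t + c)), t in degC, e_s in hPa (over water)",
    "a": 6.112,
    "b": 17.67,
    "c": 243.5
  },
  "nws_simple": {
    "comment": "HI_F = 0.5 * (T + 61.0 + (T - 68.0) * 1.2 + RH * 0.094); T in degF, RH in percent",
    "coeffs": [61.0, 68.0, 1.2, 0.094, 0.5],
    "rothfusz_switch_f": 80.0
  },
  "rothfusz": {
    "comment": "HI_F = c0 + c1*T + c2*RH + c3*T*RH + c4*T^2 + c5*RH^2 + c6*T^2*RH + c7*T*RH^2 + c8*T^2*RH^2",
    "coeffs": [-42.379, 2.04901523, 10.14333127, -0.22475541,
               -0.00683783, -0.05481717, 0.00122874, 0.00085282, -0.00000199]
  },
  "low_rh_adjustment": {
    "comment": "subtract ((13 - RH)/4) * sqrt((17 - |T - 95|)/17) when RH < 13 and 80 <= T <= 112 (T in degF)",
    "rh_max": 13.0,
    "t_range_f": [80.0, 112.0]
  },
  "high_rh_adjustment": {
    "comment": "add ((RH - 85)/10) * ((87 - T)/5) when RH > 85 and 80 <= T <= 87 (T in degF)",
    "rh_min": 85.0,
    "t_range_f": [80.0, 87.0]
  },
  "wbgt_quadratic": {
    "comment": "indoor/shaded WBGT_degC = a*HI_F^2 + b*HI_F + c at fixed 0.5 m/s wind, no radiant load",
    "a": -0.0034,
    "b": 0.96,
    "c": -34.0,
    "valid_hi_range_f": [70.0, 115.0]
  }
}
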