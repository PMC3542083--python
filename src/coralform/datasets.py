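"""Bundled reference conditions and morphometrics.

One row per colony: six simulated colonies from a diffusivity sweep at
fixed inlet speed (labels SIM_*) and five CT-scanned Pocillopora
verrucosa colonies grown under controlled flow (labels CT_*/TS_*).  The
physical parameters (velocity, viscosity, density, diffusivity, surface
diffusivity) are the study conditions; dc is the measured mean terminal
branch thickness; the remaining columns are the tabulated morphometric
measurements used by the worked examples and cross-checks.

NaN marks quantities that are undefined for a condition (e.g. viscosity
of the no-flow simulation) or were not measurable.
"""

from __future__ import annotations

import pandas as pd

_NAN = float("nan")

_ROWS = [
    # label, u (m/s), mu (Pa s), rho (kg/m3), D (m2/s), D_s (m2/s),
    # dc (m), Pe_branch, Re_branch, area (m2), volume (m3), S/V (1/m),
    # sm_mag_mean (m)
    ("SIM_NO_FLOW", 0.0, _NAN, _NAN, 1.0, 3.0e-4,
     2.42e-3, 0.0, 0.0, 4.95e-2, 1.19e-4, 416.0, 3.27e-3),
    ("SIM_FLOW_D1", 0.05, 5.0e-2, 1.0e3, 1.0e-1, 3.0e-4,
     2.26e-3, 1.13e-3, 2.26, 4.59e-2, 1.12e-4, 410.0, 3.98e-3),
    ("SIM_FLOW_D2", 0.05, 5.0e-2, 1.0e3, 1.0e-2, 3.0e-4,
     2.10e-3, 1.05e-2, 2.10, 3.64e-2, 8.98e-5, 405.0, 11.25e-3),
    ("SIM_FLOW_D3", 0.05, 5.0e-2, 1.0e3, 1.0e-3, 3.0e-4,
     1.94e-3, 9.7e-2, 1.9, 3.22e-2, 7.74e-5, 416.0, 28.77e-3),
    ("SIM_FLOW_D4", 0.05, 5.0e-2, 1.0e3, 1.0e-4, 3.0e-4,
     2.26e-3, 1.13, 2.26, 2.30e-2, 6.34e-5, 363.0, 33.45e-3),
    ("SIM_FLOW_D5", 0.05, 5.0e-2, 1.0e3, 1.0e-5, 3.0e-4,
     _NAN, 11.0, 2.0, 3.45e-2, 1.03e-4, 335.0, _NAN),
    ("CT_456", 0.05, 1.0e-3, 1.0e3, 1.0e-3, _NAN,
     2.71e-3, 1.36e-1, 135.5, 1.32e-1, 1.53e-4, 863.0, 2.4e-3),
    ("TS_002", 0.01, 1.0e-3, 1.0e3, 1.0e-3, _NAN,
     1.63e-3, 1.63e-2, 16.3, 4.97e-2, 8.46e-5, 587.0, 1.93e-3),
    ("TS_001", 0.15, 1.0e-3, 1.0e3, 1.0e-3, _NAN,
     1.25e-3, 1.88e-1, 187.5, 8.64e-2, 1.28e-4, 675.0, 3.96e-3),
    ("TS_003", 0.15, 1.0e-3, 1.0e3, 1.0e-3, _NAN,
     1.51e-3, 2.27e-1, 226.5, 4.13e-2, 7.15e-5, 578.0, 7.36e-3),
    ("CT_455", 0.15, 1.0e-3, 1.0e3, 1.0e-3, _NAN,
     1.92e-3, 2.88e-1, 288.0, 1.03e-1, 1.38e-4, 746.0, 20.53e-3),
]

_COLUMNS = ["label", "velocity", "viscosity", "density", "diffusivity",
            "surface_diffusivity", "dc", "pe_branch", "re_branch",
            "surface_area", "volume", "sv_ratio", "sm_mag_mean"]


def reference_conditions() -> pd.DataFrame:
    """The bundled per-colony condition/morphometrics table."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("label")


# (area m^2, volume m^3) pairs quoted for the compactness comparison:
# an interim diffusion-dominated colony and an advection-dominated one
SV_EXAMPLE_DIFFUSION = (2.23e-2, 7.71e-5)   # -> 289 m^-1
SV_EXAMPLE_ADVECTION = (3.22e-2, 7.74e-5)   # -> 416 m^-1


def sv_examples() -> dict[str, tuple[float, float]]:
    return {"diffusion_interim": SV_EXAMPLE_DIFFUSION,
            "advection": SV_EXAMPLE_ADVECTION}
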