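"""Steady-state oxygen diffusion with zero-order consumption in a sphere.

A spherical foraminifer of radius R sits in water of ambient dissolved
oxygen concentration C0 (mol/m^3).  Oxygen enters by Fickian diffusion
(flux J = -D dC/dr) and is consumed throughout the cytoplasm at a
constant volumetric rate Q.  At steady state the concentration obeys

    (1/r^2) d/dr (r^2 dC/dr) = Q / D,   C(R) = C0,  dC/dr|_0 = 0,

with the closed-form solution C(r) = C0 - Q (R^2 - r^2) / (6 D).  The
minimum sits at the center; the organism is viable iff the center
concentration is non-negative, which bounds the radius by the critical
value R_max = sqrt(6 D C0 / Q).  A conservative second-order finite
difference solver of the same boundary-value problem is provided as a
numerical cross-check (and extension point for non-uniform sinks).

Internal units are SI (m, mol/m^3); radii cross the interface in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

UM_PER_M = 1e6

#: Default physical constants: O2 diffusivity in cytoplasm/seawater and the
#: volumetric O2 consumption rate of benthic foraminifera at 25 degC.
D_DEFAULT = 1.7e-9  # m^2/s
Q_DEFAULT = 1.45e-3  # mol/(m^3 s)

#: Named ambient dissolved-oxygen regimes, mol/m^3.
PRESETS = {
    "oxygen_rich": 0.2,
    "hypoxic_high": 0.06,
    "hypoxic_low": 0.045,
    "suboxic": 0.005,
}


@dataclass(frozen=True)
class DiffusionScenario:
    """Physical setting: diffusivity D, consumption rate Q, ambient C0."""

    D: float = D_DEFAULT  # m^2/s
    Q: float = Q_DEFAULT  # mol/(m^3 s)
    C0: float = PRESETS["suboxic"]  # mol/m^3
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        if self.D <= 0 or self.Q <= 0 or self.C0 < 0:
            raise ValueError("require D > 0, Q > 0, C0 >= 0")

    @classmethod
    def from_preset(cls, name: str, D: float = D_DEFAULT, Q: float = Q_DEFAULT
                    ) -> "DiffusionScenario":
        return cls(D=D, Q=Q, C0=PRESETS[name], name=name)

    def with_C0(self, C0: float) -> "DiffusionScenario":
        return replace(self, C0=C0, name="custom")


@dataclass
class RadialProfile:
    """Oxygen concentration along the radius of a sphere of radius R (um)."""

    R: float  # um
    r_nodes: np.ndarray  # um, 0..R
    C_values: np.ndarray  # mol/m^3
    method: str  # "analytic" | "numeric"

    @property
    def C_center(self) -> float:
        return float(self.C_values[0])

    @property
    def viable(self) -> bool:
        return bool(self.C_values.min() >= 0.0)


def center_concentration_analytic(R_um: float, scenario: DiffusionScenario) -> float:
    """Steady-state center concentration C0 - Q R^2 / (6 D), mol/m^3.

    May be negative, which signals the sphere is not viable at this size.
    """
    if R_um <= 0:
        raise ValueError("radius must be positive")
    R = R_um / UM_PER_M
    return scenario.C0 - scenario.Q * R**2 / (6.0 * scenario.D)


def radial_profile_analytic(
    R_um: float, scenario: DiffusionScenario, n_nodes: int = 200
) -> RadialProfile:
    """Closed-form profile C(r) = C0 - Q (R^2 - r^2) / (6 D) on a uniform mesh."""
    if R_um <= 0:
        raise ValueError("radius must be positive")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    r_um = np.linspace(0.0, R_um, n_nodes)
    r = r_um / UM_PER_M
    R = R_um / UM_PER_M
    C = scenario.C0 - scenario.Q * (R**2 - r**2) / (6.0 * scenario.D)
    return RadialProfile(R=R_um, r_nodes=r_um, C_values=C, method="analytic")


def solve_radial_numeric(
    R_um: float,
    scenario: DiffusionScenario,
    n_nodes: int = 200,
    q_profile: "callable | None" = None,
) -> RadialProfile:
    """Finite-volume solution of the radial diffusion-consumption BVP.

    Conservative second-order scheme on a uniform mesh r_i = i h: face
    fluxes r_{i+1/2}^2 (C_{i+1} - C_i)/h balance the consumption
    integrated over each control volume (Simpson quadrature), with a
    zero-flux symmetry cell at the center and a fixed surface
    concentration C(R) = C0.  Solved as a tridiagonal system.

    ``q_profile(r_m) -> multiplier`` optionally modulates the consumption
    rate along the radius (dimensionless factor on Q; default uniform).
    Q = 0 (or a zero profile) returns the flat profile C0.
    """
    if R_um <= 0:
        raise ValueError("radius must be positive")
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    R = R_um / UM_PER_M
    n = n_nodes
    h = R / (n - 1)
    g = scenario.Q / scenario.D

    if q_profile is None:
        q = lambda r: np.ones_like(r)  # noqa: E731
    else:
        q = lambda r: np.asarray(q_profile(r), dtype=float)  # noqa: E731

    def cell_source(lo: float, hi: float) -> float:
        # Simpson quadrature of q(r) r^2 over one control volume
        mid = 0.5 * (lo + hi)
        pts = np.array([lo, mid, hi])
        vals = q(pts) * pts**2
        return float((hi - lo) / 6.0 * (vals[0] + 4.0 * vals[1] + vals[2]))

    # unknowns C_0 .. C_{n-1}; banded matrix (1 super, 1 sub diagonal)
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    # center control volume [0, h/2]: outward flux only
    f0 = (0.5 * h) ** 2 / h
    ab[1, 0] = -f0
    ab[0, 1] = f0
    rhs[0] = g * cell_source(0.0, 0.5 * h)
    for i in range(1, n - 1):
        r_i = i * h
        w_plus = (r_i + 0.5 * h) ** 2 / h
        w_minus = (r_i - 0.5 * h) ** 2 / h
        ab[0, i + 1] = w_plus
        ab[1, i] = -(w_plus + w_minus)
        ab[2, i - 1] = w_minus
        rhs[i] = g * cell_source(r_i - 0.5 * h, r_i + 0.5 * h)
    # surface Dirichlet node
    ab[1, n - 1] = 1.0
    ab[2, n - 2] = 0.0
    rhs[n - 1] = scenario.C0

    C = solve_banded((1, 1), ab, rhs)
    r_um = np.linspace(0.0, R_um, n)
    return RadialProfile(R=R_um, r_nodes=r_um, C_values=C, method="numeric")


def is_viable(R_um: float, scenario: DiffusionScenario) -> bool:
    """True iff the center (the profile minimum) stays non-negative."""
    return center_concentration_analytic(R_um, scenario) >= 0.0


def max_radius(scenario: DiffusionScenario) -> float:
    """Largest viable sphere radius R_max = sqrt(6 D C0 / Q), in um."""
    if scenario.C0 == 0:
        return 0.0
    return math.sqrt(6.0 * scenario.D * scenario.C0 / scenario.Q) * UM_PER_M


def max_log10_volume(scenario: DiffusionScenario) -> float:
    """log10 of the maximum sustainable spherical test volume, log10 um^3."""
    r = max_radius(scenario)
    if r <= 0:
        raise ValueError("no viable size at zero ambient oxygen")
    return math.log10(4.0 / 3.0 * math.pi * r**3)


def center_concentration_curve(
    radii_um: Sequence[float],
    scenarios: Iterable[DiffusionScenario],
) -> pd.DataFrame:
    """Tidy table of center concentration vs radius for several scenarios.

    Columns: scenario, C0, R_um, C_center, viable.
    """
    radii = np.asarray(radii_um, dtype=float)
    if radii.size == 0 or np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    rows = []
    for sc in scenarios:
        for r in radii:
            c = center_concentration_analytic(float(r), sc)
            rows.append(
                {"scenario": sc.name, "C0": sc.C0, "R_um": float(r),
                 "C_center": c, "viable": c >= 0.0}
            )
    return pd.DataFrame(rows)
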