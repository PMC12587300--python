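"""Degradation-quantity and mass-balance accounting.

This module turns measured iron pools into degraded-toluene equivalents and
closes the toluene budget of a column run:

* :func:`integrate_solid_fe` — total solid-phase Fe(II) mass from an
  end-of-run concentration profile (mg/kg dry medium vs distance), the
  solid-phase audit of iron-coupled degradation;
* :func:`integrate_dissolved_flux` — the "classical" dissolved-only estimate,
  a time integral of dissolved Fe²⁺ flux past a sampling port;
* :func:`partition_fractions` — solid vs dissolved percentage split;
* :func:`mass_balance` — inflow/outflow/degraded bookkeeping and the
  residual attributable to sorption or non-iron removal pathways.

The dissolved-only estimate systematically recovers only the mobile fraction
f_d of total Fe(II) production — the quantitative reason dissolved-phase
monitoring alone underestimates iron-coupled natural attenuation by a factor
of ~50-100 when ~98 % of the Fe(II) stays in the solid phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .column import ColumnSpec
from .stoichiometry import StoichiometryModel, round_sig

__all__ = [
    "SolidFeProfile",
    "SolidFeMass",
    "MassBalanceReport",
    "integrate_solid_fe",
    "integrate_dissolved_flux",
    "flux_mass",
    "conservative_inflow",
    "partition_fractions",
    "mass_balance",
]

#: mL/min → L/day
_ML_MIN_TO_L_DAY = 1440.0 / 1000.0


@dataclass(frozen=True)
class SolidFeProfile:
    """End-of-run solid-phase Fe(II) profile.

    ``distance_m`` strictly increasing within [0, column length];
    ``fe2_mg_per_kg`` is mg Fe(II) per kg dry medium.
    """

    distance_m: np.ndarray
    fe2_mg_per_kg: np.ndarray
    column_id: str = ""
    day: float = float("nan")

    def __post_init__(self):
        d = np.asarray(self.distance_m, dtype=float)
        c = np.asarray(self.fe2_mg_per_kg, dtype=float)
        object.__setattr__(self, "distance_m", d)
        object.__setattr__(self, "fe2_mg_per_kg", c)
        if d.size != c.size:
            raise ValueError("distance and concentration arrays differ in length")
        if d.size and (np.diff(d) <= 0).any():
            raise ValueError("profile distances must be strictly increasing")
        if d.size and d[0] < -1e-12:
            raise ValueError("profile distances must be >= 0")
        if (c < 0).any():
            raise ValueError("solid Fe(II) concentrations must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column_id: str = "", day: float = float("nan")):
        cid = column_id or (str(df["column_id"].iloc[0]) if "column_id" in df else "")
        dday = day if day == day else (float(df["day"].iloc[0]) if "day" in df else float("nan"))
        return cls(
            distance_m=df["distance_m"].to_numpy(dtype=float),
            fe2_mg_per_kg=df["fe2_mg_per_kg"].to_numpy(dtype=float),
            column_id=cid,
            day=dday,
        )


class SolidFeMass(NamedTuple):
    """Integrated solid Fe(II) mass plus the interpolation method used."""

    mass_mg: float
    method: str


def _exp_decay(x, a, b):
    return a * np.exp(-b * x)


def integrate_solid_fe(
    profile: Union[SolidFeProfile, pd.DataFrame],
    spec: ColumnSpec,
    method: str = "trapezoid",
) -> SolidFeMass:
    """Total solid-phase Fe(II) mass (mg) in the column from a profile.

    mass = ∫₀ᴸ c(x) ρ_b A dx with c interpolated either piecewise-linearly
    (``trapezoid``, end samples extrapolated as constants to the column ends)
    or by a least-squares single-exponential decay integrated analytically
    (``fit_then_integrate``, falling back to trapezoid with a warning if the
    fit fails).

    A uniform profile c₀ returns exactly c₀ × dry mass of the packing.
    """
    if isinstance(profile, pd.DataFrame):
        profile = SolidFeProfile.from_frame(profile)
    x = profile.distance_m
    c = profile.fe2_mg_per_kg
    if x.size < 2:
        raise ValueError(f"need at least 2 profile points, got {x.size}")
    if x[-1] > spec.length + 1e-9:
        raise ValueError(
            f"profile extends to {x[-1]} m beyond column length {spec.length} m"
        )
    mass_per_m = spec.bulk_density * 1000.0 * spec.cross_section_area  # kg/m

    if method == "trapezoid":
        integral = float(np.trapezoid(c, x))
        integral += c[0] * (x[0] - 0.0) + c[-1] * (spec.length - x[-1])
        return SolidFeMass(integral * mass_per_m, "trapezoid")
    if method == "fit_then_integrate":
        try:
            if c.max() <= 0:
                raise RuntimeError("all-zero profile")
            p0 = (max(c[0], c.max() * 0.5), 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _exp_decay, x, c, p0=p0, maxfev=10000,
                    bounds=([0.0, 1e-9], [np.inf, np.inf]),
                )
            a, b = popt
            integral = a / b * (1.0 - np.exp(-b * spec.length))
            return SolidFeMass(float(integral) * mass_per_m, "fit_then_integrate")
        except (RuntimeError, ValueError) as err:
            warnings.warn(
                f"exponential fit failed ({err}); falling back to trapezoid",
                stacklevel=2,
            )
            return SolidFeMass(
                integrate_solid_fe(profile, spec, "trapezoid").mass_mg,
                "trapezoid (fit fallback)",
            )
    raise ValueError(f"unknown method {method!r}; use 'trapezoid' or 'fit_then_integrate'")


def _series_mass(
    days: np.ndarray, conc_mg_l: np.ndarray, q_ml_min: float
) -> float:
    """Trapezoid ∫ C(t)·Q dt over the sampled days, mg."""
    q_l_day = q_ml_min * _ML_MIN_TO_L_DAY
    return float(np.trapezoid(conc_mg_l, days)) * q_l_day


def flux_mass(
    series: pd.DataFrame,
    q_ml_min: float,
    value_col: str = "value",
    censored_as: str = "zero",
) -> float:
    """Mass (mg) carried past a point: trapezoid of C(t)·Q over sampling days.

    ``series`` needs ``day`` and ``value_col`` columns (mg/L), time-sorted;
    censored rows (if a ``censored`` column exists) contribute 0
    (``censored_as='zero'``, conservative) or half the detection limit
    (``censored_as='half'``).
    """
    if series.empty:
        raise ValueError("empty series")
    days = series["day"].to_numpy(dtype=float)
    if (np.diff(days) < 0).any():
        raise ValueError("series must be sorted by day")
    if (np.diff(days) == 0).any():
        raise ValueError("duplicate days in series")
    conc = series[value_col].to_numpy(dtype=float).copy()
    if "censored" in series:
        cens = series["censored"].to_numpy(dtype=bool)
        if censored_as == "zero":
            conc[cens] = 0.0
        elif censored_as == "half":
            conc[cens] = series["detection_limit"].to_numpy(dtype=float)[cens] / 2.0
        else:
            raise ValueError(f"censored_as must be 'zero' or 'half', got {censored_as!r}")
    return _series_mass(days, conc, q_ml_min)


def integrate_dissolved_flux(
    table: pd.DataFrame,
    q_ml_min: float,
    port: Optional[float] = None,
    mode: str = "port",
    censored_as: str = "zero",
) -> tuple[float, float]:
    """Dissolved Fe²⁺ mass (mg) past a port — the classical monitoring method.

    ``table`` is a monitoring table (or subset) holding the ``fe2_dissolved``
    analyte in mg/L.  With ``mode='port'`` the given ``port`` distance is
    integrated; with ``mode='peak'`` every port is integrated and the maximum
    is returned (the "position of peak generation" convention).

    Returns
    -------
    (mass_mg, port_m)
    """
    sub = table
    if "analyte" in sub:
        sub = sub[sub["analyte"] == "fe2_dissolved"]
    if sub.empty:
        raise ValueError("no dissolved-Fe rows in table")
    if mode == "port":
        if port is None:
            raise ValueError("mode='port' requires a port distance")
        at = sub[np.isclose(sub["distance_m"].astype(float), port)]
        if at.empty:
            raise ValueError(f"no rows at port {port} m")
        return flux_mass(at.sort_values("day"), q_ml_min, censored_as=censored_as), float(port)
    if mode == "peak":
        best = (-np.inf, float("nan"))
        for p, at in sub.groupby("distance_m"):
            m = flux_mass(at.sort_values("day"), q_ml_min, censored_as=censored_as)
            if m > best[0]:
                best = (m, float(p))
        return best
    raise ValueError(f"mode must be 'port' or 'peak', got {mode!r}")


def conservative_inflow(
    control_effluent: pd.DataFrame,
    q_ml_min: float,
    duration_days: float,
    late_window: tuple[float, float],
) -> float:
    """Conservative influent mass estimate (mg) from control-column equilibrium.

    Mean effluent concentration (mg/L) of a sterile control over the late
    window, times Q and the full duration — the influent proxy that already
    discounts preparation/volatilisation losses.
    """
    lo, hi = late_window
    win = control_effluent[
        (control_effluent["day"] >= lo) & (control_effluent["day"] <= hi)
    ]
    if win.empty:
        raise ValueError(f"empty late window [{lo}, {hi}] in control effluent")
    col = "value" if "value" in win else "toluene_mg_l"
    c_eq = float(win[col].mean())
    return c_eq * q_ml_min * _ML_MIN_TO_L_DAY * duration_days


def partition_fractions(m_solid_mg: float, m_dissolved_mg: float) -> tuple[float, float]:
    """Percentage split of Fe(II) between solid and dissolved phases.

    (42, 0.72) → (98.3 %, 1.7 %).  Raises if both masses are zero.
    """
    if m_solid_mg < 0 or m_dissolved_mg < 0:
        raise ValueError("phase masses must be >= 0")
    total = m_solid_mg + m_dissolved_mg
    if total == 0:
        raise ValueError("partition undefined: both phase masses are zero")
    return 100.0 * m_solid_mg / total, 100.0 * m_dissolved_mg / total


@dataclass(frozen=True)
class MassBalanceReport:
    """Toluene budget of one column run (all masses mg).

    ``discrepancy`` = (inflow − outflow) − degraded_solid_method: removal not
    explained by iron-coupled degradation (sorption, side reactions, losses).
    """

    inflow_mass: float
    outflow_mass: float
    degraded_solid_method: float
    degraded_dissolved_method: float
    removed_total: float
    discrepancy: float
    partition_solid_pct: float
    partition_dissolved_pct: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def rounded(self, sig: int = 2) -> dict[str, float]:
        """Display form, 2-significant-figure convention."""
        return {k: round_sig(v, sig) for k, v in self.as_dict().items()}


def mass_balance(
    inflow_mg: float,
    outflow_mg: float,
    degraded_solid_mg: float,
    degraded_dissolved_mg: float = 0.0,
) -> MassBalanceReport:
    """Assemble the toluene mass-balance report from already-integrated masses.

    Use :func:`flux_mass` / :func:`conservative_inflow` to obtain the inflow
    and outflow masses from concentration series.  Example: inflow 12 mg,
    outflow 0.03 mg, degraded (solid method) 1.9 mg → removed 11.97 mg and a
    discrepancy of 10.07 mg attributable to non-iron pathways.
    """
    for name, v in [("inflow_mg", inflow_mg), ("outflow_mg", outflow_mg),
                    ("degraded_solid_mg", degraded_solid_mg),
                    ("degraded_dissolved_mg", degraded_dissolved_mg)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    removed = inflow_mg - outflow_mg
    if degraded_solid_mg + degraded_dissolved_mg > 0:
        p_solid, p_diss = partition_fractions(degraded_solid_mg, degraded_dissolved_mg)
    else:
        p_solid = p_diss = float("nan")
    return MassBalanceReport(
        inflow_mass=inflow_mg,
        outflow_mass=outflow_mg,
        degraded_solid_method=degraded_solid_mg,
        degraded_dissolved_method=degraded_dissolved_mg,
        removed_total=removed,
        discrepancy=removed - degraded_solid_mg,
        partition_solid_pct=p_solid,
        partition_dissolved_pct=p_diss,
    )
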