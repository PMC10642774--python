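"""Radiocarbon (14C) tracer dynamics through compartmental systems.

The 14C sub-system of a (possibly time-dependent) compartmental system
shares the transport operator of bulk carbon and adds radioactive decay:

    dx14/dt = u(t) * F_atm(t) + (B(t) - lambda I) x14,

where ``F_atm = 1 + Delta14C_atm/1000`` is the fraction modern of the
atmospheric source and ``lambda = ln 2 / 5730 yr^-1``.  Pool and
respiration signatures are reported as per-mil deviations,
``Delta14C = 1000 (x14/x - 1)``; conventionally Delta14C histories are
fractionation-corrected, so no isotopic fractionation is applied on
uptake or respiration.

The atmospheric history can be read from a Graven-style CSV (columns
``year``, ``delta14c``, optional ``zone``) or emulated by a synthetic
bomb curve (pre-bomb plateau near 0 permil, spike to several hundred
permil in the early 1960s, exponential relaxation after), so the tracer
machinery is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

from .core import CompartmentalError
from .nonautonomous import TimeDependentSystem, solve_trajectory

__all__ = [
    "LAMBDA_14C",
    "AtmosphericC14Curve",
    "read_atm_curve",
    "synthetic_bomb_curve",
    "RadiocarbonRun",
    "solve_radiocarbon",
    "scenario_delta_difference",
]

#: decay constant for the 5730-yr half-life (yr^-1)
LAMBDA_14C = float(np.log(2.0) / 5730.0)


@dataclass(frozen=True)
class AtmosphericC14Curve:
    """Tabulated atmospheric Delta14C history (permil vs calendar year).

    Queries interpolate linearly between tabulated years and extrapolate
    as constants outside the tabulated span.
    """

    years: NDArray[np.float64]
    delta14c: NDArray[np.float64]
    zone: str | None = None

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        vals = np.asarray(self.delta14c, dtype=float)
        if years.ndim != 1 or years.shape != vals.shape or len(years) < 2:
            raise ValueError("curve needs matching 1-D year/value arrays with >= 2 rows")
        if np.any(np.diff(years) <= 0):
            bad = int(np.argmax(np.diff(years) <= 0)) + 1
            raise ValueError(f"years not strictly increasing at row {bad}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "delta14c", vals)

    def delta14c_at(self, t):
        """Delta14C (permil) at calendar time(s) ``t``."""
        return np.interp(t, self.years, self.delta14c)

    def fraction_modern(self, t):
        """Atmospheric fraction modern F = 1 + Delta14C/1000."""
        return 1.0 + self.delta14c_at(t) / 1000.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "delta14c": self.delta14c})
        if self.zone is not None:
            df["zone"] = self.zone
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_atm_curve(path) -> AtmosphericC14Curve:
    """Parse a Graven-style CSV with columns ``year``, ``delta14c`` and
    an optional ``zone`` label."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"year", "delta14c"} - set(df.columns)
    if missing:
        raise ValueError(f"atmospheric curve is missing column(s): {sorted(missing)}")
    zone = None
    if "zone" in df.columns and len(df):
        zones = df["zone"].unique()
        if len(zones) > 1:
            raise ValueError(f"curve file mixes zones {list(zones)}; filter to one zone first")
        zone = str(zones[0])
    return AtmosphericC14Curve(years=df["year"].to_numpy(float), delta14c=df["delta14c"].to_numpy(float), zone=zone)


def synthetic_bomb_curve(
    *,
    peak_year: float = 1964.0,
    peak_value: float = 700.0,
    decline_rate: float = 0.06,
    rise_years: float = 9.0,
    suess_permil: float = 0.0,
    t_start: float = 1850.0,
    t_end: float = 2025.0,
    seed: int | None = None,
    jitter_permil: float = 0.0,
) -> AtmosphericC14Curve:
    """Deterministic stand-in for the observed atmospheric Delta14C history.

    Synthetic curve (labelled as such in its zone): a pre-bomb plateau
    at 0 permil (optionally ramping to ``-suess_permil`` by 1950 to mimic
    the Suess effect), a smooth rise over ``rise_years`` to
    ``peak_value`` permil at ``peak_year``, and an exponential relaxation
    toward 0 at ``decline_rate`` (yr^-1) afterwards.  ``jitter_permil``
    adds seeded measurement-like noise (off by default).
    """
    if peak_value <= 0:
        raise ValueError("peak_value must be positive")
    years = np.arange(t_start, t_end + 0.5, 1.0)
    vals = np.zeros_like(years)
    pre = years <= 1950.0
    if suess_permil:
        ramp = np.clip((years - 1890.0) / (1950.0 - 1890.0), 0.0, 1.0)
        vals[pre] = -suess_permil * ramp[pre]
    base_1950 = vals[years <= 1950.0][-1] if pre.any() else 0.0
    rise = (years > peak_year - rise_years) & (years <= peak_year)
    s = (years[rise] - (peak_year - rise_years)) / rise_years
    vals[rise] = base_1950 + (peak_value - base_1950) * s**3  # slow start, sharp spike
    post = years > peak_year
    vals[post] = peak_value * np.exp(-decline_rate * (years[post] - peak_year))
    if jitter_permil:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, jitter_permil, size=vals.shape)
    return AtmosphericC14Curve(years=years, delta14c=vals, zone="synthetic")


@dataclass
class RadiocarbonRun:
    """14C stocks and Delta14C signatures over a simulation."""

    times: NDArray[np.float64]
    x: NDArray[np.float64]  # bulk stocks (PgC), shape (t, n)
    x14: NDArray[np.float64]  # fraction-modern-weighted 14C stocks, shape (t, n)
    delta_pools: NDArray[np.float64]  # permil, shape (t, n)
    delta_resp: NDArray[np.float64]  # permil, shape (t,)
    curve: AtmosphericC14Curve
    lam: float = LAMBDA_14C

    def to_frame(self, names: tuple[str, ...] | None = None) -> pd.DataFrame:
        names = names or tuple(f"pool_{i + 1}" for i in range(self.x.shape[1]))
        data = {
            "year": self.times,
            "delta14c_atm": self.curve.delta14c_at(self.times),
            "delta14c_resp": self.delta_resp,
        }
        for j, nm in enumerate(names):
            data[f"delta14c_{nm}"] = self.delta_pools[:, j]
        return pd.DataFrame(data)


def solve_radiocarbon(
    tds: TimeDependentSystem,
    curve: AtmosphericC14Curve,
    t_grid: ArrayLike,
    *,
    lam: float = LAMBDA_14C,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> RadiocarbonRun:
    """Run the 14C tracer alongside the bulk carbon.

    Spin-up is analytic: the tracer starts at the equilibrium of the
    base system with the atmosphere pinned at the curve's value at the
    start time, ``x14(t_start) = -(B - lam I)^-1 u F_atm(t_start)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    B0, u0 = tds.base.B, tds.base.u
    n = tds.n
    A0 = B0 - lam * np.eye(n)
    try:
        x14_0 = np.linalg.solve(A0, -u0 * curve.fraction_modern(t_grid[0]))
    except np.linalg.LinAlgError as exc:
        raise CompartmentalError(f"(B - lambda I) is singular: {exc}") from exc
    sol = solve_ivp(
        lambda t, y: tds.u_t(t) * curve.fraction_modern(t) + (tds.B_t(t) - lam * np.eye(n)) @ y,
        (float(t_grid[0]), float(t_grid[-1])),
        x14_0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"radiocarbon solver failed: {sol.message}")
    x14 = np.clip(sol.y.T, 0.0, None)
    x = solve_trajectory(tds, t_grid, rtol=rtol, atol=atol) if t_grid[0] >= tds.t0 else None
    if x is None:
        raise ValueError("radiocarbon grid must start at or after the system's t0")
    delta_pools = 1000.0 * (x14 / x - 1.0)
    z = np.array([tds.release_rates(float(t)) for t in t_grid])
    delta_resp = 1000.0 * (np.einsum("ti,ti->t", z, x14) / np.einsum("ti,ti->t", z, x) - 1.0)
    return RadiocarbonRun(times=t_grid, x=x, x14=x14, delta_pools=delta_pools, delta_resp=delta_resp, curve=curve, lam=lam)


def scenario_delta_difference(run: RadiocarbonRun, reference: RadiocarbonRun) -> pd.DataFrame:
    """Respired Delta14C difference, scenario minus equilibrium reference.

    Positive values mean the scenario respires carbon with a higher
    radiocarbon signature than the system at equilibrium.  Both runs
    must share the time grid and atmospheric curve.
    """
    if run.times.shape != reference.times.shape or not np.allclose(run.times, reference.times):
        raise ValueError("runs are on different time grids")
    if run.curve is not reference.curve and not (
        np.array_equal(run.curve.years, reference.curve.years)
        and np.array_equal(run.curve.delta14c, reference.curve.delta14c)
    ):
        raise ValueError("runs use different atmospheric curves")
    return pd.DataFrame({"year": run.times, "delta14c_diff": run.delta_resp - reference.delta_resp})
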