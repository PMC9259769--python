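"""Enzyme characterization mathematics.

Purification-table arithmetic, Michaelis-Menten and biphasic (two-regime)
saturation fits, IC50 by semilog interpolation, inhibition-type
classification from Km/Vmax shifts, Arrhenius activation energy and
first-order thermal-inactivation half-life.

Units follow bench convention: substrate in mM, velocities in
umol/min/mg protein, inhibitor concentrations in uM, temperatures in K for
Arrhenius fits, time in minutes, activation energy in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "RateDataset",
    "MMFit",
    "BiphasicFit",
    "IC50Result",
    "InhibitionResult",
    "ArrheniusFit",
    "DecayFit",
    "FitError",
    "purification_stats",
    "michaelis_menten",
    "fit_michaelis_menten",
    "fit_biphasic",
    "ic50",
    "classify_inhibition",
    "arrhenius_energy",
    "half_life",
]

# Gas constant in kcal/(mol K), so activation energies come out in kcal/mol.
R_KCAL = 0.0019872


class FitError(RuntimeError):
    """A fit failed; carries whatever linearized estimate was available."""

    def __init__(self, message: str, fallback: dict | None = None):
        super().__init__(message)
        self.fallback = fallback or {}


@dataclass(frozen=True)
class RateDataset:
    """Initial-velocity data: substrate (mM, strictly increasing) vs velocity."""

    concentrations: np.ndarray
    velocities: np.ndarray
    substrate: str = ""
    temperature_c: float = 25.0

    def __post_init__(self) -> None:
        s = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "concentrations", s)
        object.__setattr__(self, "velocities", v)
        if s.shape != v.shape:
            raise ValueError("concentration and velocity arrays differ in length")
        if (s <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(s) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")


def purification_stats(
    steps: list[tuple[str, float, float]],
    crude: str = "Crude extract",
    pooled: list[str] | None = None,
) -> pd.DataFrame:
    """Derive specific activity, purification fold and recovery per step.

    ``steps`` holds (step name, total activity in units, total protein in mg).
    Fold is step specific activity over the crude step's; recovery is step
    activity over crude activity x 100. ``pooled`` names steps whose summed
    activity is reported as an extra "Pooled" row (e.g. final fractions).
    """
    names = [s[0] for s in steps]
    if crude not in names:
        raise ValueError(f"crude step {crude!r} not present")
    if any(p <= 0 for _, _, p in steps):
        raise ValueError("protein must be positive in every step")
    df = pd.DataFrame(steps, columns=["step", "activity_units", "protein_mg"])
    df["specific_activity"] = df.activity_units / df.protein_mg
    crude_row = df.loc[df.step == crude].iloc[0]
    df["fold"] = df.specific_activity / crude_row.specific_activity
    df["recovery_pct"] = 100.0 * df.activity_units / crude_row.activity_units
    if pooled:
        act = df.loc[df.step.isin(pooled), "activity_units"].sum()
        prot = df.loc[df.step.isin(pooled), "protein_mg"].sum()
        row = {
            "step": "Pooled(" + "+".join(pooled) + ")",
            "activity_units": act,
            "protein_mg": prot,
            "specific_activity": act / prot,
            "fold": (act / prot) / crude_row.specific_activity,
            "recovery_pct": 100.0 * act / crude_row.activity_units,
        }
        df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df


def michaelis_menten(s, vmax: float, km: float):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))


@dataclass(frozen=True)
class MMFit:
    km: float              # mM
    vmax: float            # umol/min/mg
    rss: float
    method: str = "nls"
    converged: bool = True
    km_se: float | None = None
    vmax_se: float | None = None

    def __post_init__(self) -> None:
        if self.km <= 0 or self.vmax <= 0:
            raise ValueError("Km and Vmax must be positive")


def _lineweaver_burk_seed(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Double-reciprocal linear estimate used to initialize the NLS fit."""
    mask = v > 0
    res = stats.linregress(1.0 / s[mask], 1.0 / v[mask])
    vmax = 1.0 / res.intercept if res.intercept > 0 else float(v.max())
    km = res.slope * vmax if res.slope * vmax > 0 else float(np.median(s))
    return km, vmax


def fit_michaelis_menten(data: RateDataset) -> MMFit:
    """Nonlinear least squares of v = Vmax*S/(Km+S)."""
    s, v = data.concentrations, data.velocities
    if len(s) < 4:
        raise ValueError("need at least 4 points for a saturation fit")
    km0, vmax0 = _lineweaver_burk_seed(s, v)
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"Michaelis-Menten fit did not converge: {exc}",
            fallback={"km": km0, "vmax": vmax0, "method": "lineweaver_burk"},
        ) from exc
    vmax, km = popt
    rss = float(np.sum((v - michaelis_menten(s, vmax, km)) ** 2))
    se = np.sqrt(np.diag(pcov))
    return MMFit(km=float(km), vmax=float(vmax), rss=rss,
                 vmax_se=float(se[0]), km_se=float(se[1]))


@dataclass(frozen=True)
class BiphasicFit:
    """Two Michaelian regimes split at a breakpoint concentration.

    Describes concave-downward (non-Michaelian) saturation behaviour where
    low- and high-concentration ranges show distinct apparent Km values.
    """

    breakpoint: float
    low: MMFit
    high: MMFit
    breakpoint_mode: str = "fixed"

    @property
    def rss(self) -> float:
        return self.low.rss + self.high.rss


def _split(data: RateDataset, bp: float) -> tuple[RateDataset, RateDataset]:
    s, v = data.concentrations, data.velocities
    lo = s <= bp
    hi = s >= bp  # the breakpoint concentration anchors both regimes
    return (
        RateDataset(s[lo], v[lo], data.substrate, data.temperature_c),
        RateDataset(s[hi], v[hi], data.substrate, data.temperature_c),
    )


def fit_biphasic(data: RateDataset, breakpoint: float | None = None) -> BiphasicFit:
    """Independent per-regime Michaelis-Menten fits.

    With a fixed ``breakpoint`` each regime must hold >= 4 points; with
    ``breakpoint=None`` every observed concentration admitting 4 points per
    side is scanned and the split minimizing total RSS is kept.
    """
    if breakpoint is not None:
        lo, hi = _split(data, breakpoint)
        if len(lo.concentrations) < 4 or len(hi.concentrations) < 4:
            raise ValueError(
                f"breakpoint {breakpoint} leaves a regime with fewer than 4 points"
            )
        return BiphasicFit(breakpoint=breakpoint,
                           low=fit_michaelis_menten(lo),
                           high=fit_michaelis_menten(hi))
    best = None
    for bp in data.concentrations:
        lo, hi = _split(data, float(bp))
        if len(lo.concentrations) < 4 or len(hi.concentrations) < 4:
            continue
        try:
            fit = BiphasicFit(breakpoint=float(bp),
                              low=fit_michaelis_menten(lo),
                              high=fit_michaelis_menten(hi),
                              breakpoint_mode="scan")
        except (FitError, ValueError):
            continue
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        raise FitError("no breakpoint admits 4 points in each regime")
    return best


@dataclass(frozen=True)
class IC50Result:
    ic50_um: float | None
    censored: bool
    detail: str = ""


def ic50(concentrations_um, percent_activity) -> IC50Result:
    """IC50 by linear interpolation of % activity against log10(concentration).

    Requires observed activities to bracket 50%; extrapolation beyond the
    tested range is refused (a censored result, not a number). An exact 50%
    observation is returned directly.
    """
    c = np.asarray(concentrations_um, dtype=float)
    a = np.asarray(percent_activity, dtype=float)
    if c.shape != a.shape or len(c) < 2:
        raise ValueError("need matched concentration/activity arrays, >= 2 points")
    if (c <= 0).any():
        raise ValueError("inhibitor concentrations must be positive")
    order = np.argsort(c)
    c, a = c[order], a[order]
    exact = np.isclose(a, 50.0)
    if exact.any():
        val = float(c[exact][0])
        return IC50Result(ic50_um=val, censored=False, detail="exact 50% observed")
    for i in range(len(c) - 1):
        if (a[i] - 50.0) * (a[i + 1] - 50.0) < 0:
            lo, hi = np.log10(c[i]), np.log10(c[i + 1])
            frac = (a[i] - 50.0) / (a[i] - a[i + 1])
            return IC50Result(
                ic50_um=float(10.0 ** (lo + frac * (hi - lo))),
                censored=False,
                detail=f"interpolated between {c[i]} and {c[i + 1]} uM",
            )
    return IC50Result(ic50_um=None, censored=True,
                      detail="activities never bracket 50%")


@dataclass(frozen=True)
class InhibitionResult:
    inhibition_type: str   # 'competitive' | 'noncompetitive' | 'mixed' | 'none'
    km_ratio: float
    vmax_ratio: float
    ic50: IC50Result | None = None
    trace: dict = field(default_factory=dict)


def classify_inhibition(
    control: MMFit,
    inhibited: MMFit,
    km_ratio_threshold: float = 1.5,
    vmax_drop_threshold: float = 0.15,
    ic50_result: IC50Result | None = None,
) -> InhibitionResult:
    """Type the inhibition from the Km/Vmax shift at fixed inhibitor.

    competitive: Km raised >= km_ratio_threshold-fold with Vmax within
    +-vmax_drop_threshold; noncompetitive: Km unchanged (within the same
    band) with Vmax reduced by >= vmax_drop_threshold; mixed: both effects;
    'none' when neither parameter moves.
    """
    km_ratio = inhibited.km / control.km
    vmax_ratio = inhibited.vmax / control.vmax
    km_up = km_ratio >= km_ratio_threshold
    vmax_down = vmax_ratio <= 1.0 - vmax_drop_threshold
    if km_up and vmax_down:
        kind = "mixed"
    elif km_up:
        kind = "competitive"
    elif vmax_down:
        kind = "noncompetitive"
    else:
        kind = "none"
    return InhibitionResult(
        inhibition_type=kind,
        km_ratio=km_ratio,
        vmax_ratio=vmax_ratio,
        ic50=ic50_result,
        trace={
            "km_ratio": km_ratio,
            "vmax_ratio": vmax_ratio,
            "km_ratio_threshold": km_ratio_threshold,
            "vmax_drop_threshold": vmax_drop_threshold,
            "km_raised": bool(km_up),
            "vmax_reduced": bool(vmax_down),
        },
    )


@dataclass(frozen=True)
class ArrheniusFit:
    ea_kcal_mol: float
    ln_a: float
    r_squared: float
    fit_range_k: tuple[float, float]
    n: int


def arrhenius_energy(temperatures_k, rates) -> ArrheniusFit:
    """Activation energy from the slope of ln(rate) against 1/T.

    Callers should restrict input to the rising phase of the activity curve
    (below the onset of denaturation); Ea = -slope * R in kcal/mol.
    """
    t = np.asarray(temperatures_k, dtype=float)
    k = np.asarray(rates, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures")
    if (t <= 0).any() or (k <= 0).any():
        raise ValueError("temperatures (K) and rates must be positive")
    res = stats.linregress(1.0 / t, np.log(k))
    return ArrheniusFit(
        ea_kcal_mol=float(-res.slope * R_KCAL),
        ln_a=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        fit_range_k=(float(t.min()), float(t.max())),
        n=len(t),
    )


@dataclass(frozen=True)
class DecayFit:
    t_half_min: float | None
    rate_constant: float | None
    censored: bool
    window_min: float
    flagged_points: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.t_half_min is not None and self.t_half_min <= 0:
            raise ValueError("half-life must be positive")


def half_life(timepoints_min, residual_activity_pct,
              outlier_rise_factor: float = 1.1) -> DecayFit:
    """First-order inactivation: fit ln(activity) vs time, t1/2 = ln2 / k.

    If activity never drops below 50% within the observation window the
    half-life is censored (reported as exceeding the window). Points where
    activity rises grossly above the previous value are flagged, not fatal.
    """
    t = np.asarray(timepoints_min, dtype=float)
    a = np.asarray(residual_activity_pct, dtype=float)
    if t.shape != a.shape or len(t) < 3:
        raise ValueError("need matched time/activity arrays, >= 3 points")
    order = np.argsort(t)
    t, a = t[order], a[order]
    flagged = tuple(
        int(i) for i in range(1, len(a)) if a[i] > outlier_rise_factor * a[i - 1]
    )
    window = float(t.max())
    if a.min() > 50.0:
        return DecayFit(t_half_min=None, rate_constant=None, censored=True,
                        window_min=window, flagged_points=flagged)
    mask = a > 0
    res = stats.linregress(t[mask], np.log(a[mask]))
    k = -res.slope
    if k <= 0:
        return DecayFit(t_half_min=None, rate_constant=None, censored=True,
                        window_min=window, flagged_points=flagged)
    return DecayFit(
        t_half_min=float(np.log(2.0) / k),
        rate_constant=float(k),
        censored=False,
        window_min=window,
        flagged_points=flagged,
    )
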