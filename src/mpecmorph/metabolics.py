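"""Enhancement factors and glucose uptake rates from replicate time series.

The enhancement factor of a secondary metabolite is the ratio of the mean
amount measured in a microparticle run to the mean amount in the
particle-free control,

    EF = mean(treatment) / mean(control),

computed per metabolite, sampling time and talc condition. Its confidence
band is obtained by the delta method on the log-ratio (treatment and
control means treated as independent) with Student-t quantiles, and a
Welch t-test compares the underlying replicate amounts.

The volumetric glucose uptake rate is the negative time derivative of the
glucose concentration curve. The per-time replicate means are fitted with
a cubic B-spline (interpolating by default, optional smoothing for noisy
data) and the spline is differentiated analytically; the rate is reported
positive for consumption, in g GLU L⁻¹ h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.interpolate import BSpline, make_interp_spline, splrep

from .stats import t_test_p

__all__ = [
    "CultureTimeSeries",
    "EnhancementResult",
    "UptakeProfile",
    "enhancement_factor",
    "enhancement_table",
    "fit_concentration_spline",
    "uptake_rate",
    "glucose_uptake_profiles",
    "timeseries_to_frame",
    "frame_to_timeseries",
]


@dataclass(frozen=True)
class CultureTimeSeries:
    """One replicate's time course of metabolite amounts and glucose.

    ``amounts`` maps metabolite name to an array over ``times_h``;
    oxytetracycline is in mg L⁻¹, the other metabolites are ion-peak
    areas in arbitrary units. ``glucose_g_per_l`` is in g L⁻¹.
    """

    talc_g_per_l: float
    replicate: int
    times_h: np.ndarray
    amounts: dict[str, np.ndarray]
    glucose_g_per_l: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        if t.ndim != 1 or t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be 1-D and strictly increasing")
        object.__setattr__(self, "times_h", t)
        amounts = {}
        for name, a in self.amounts.items():
            a = np.asarray(a, dtype=float)
            if a.shape != t.shape:
                raise ValueError(f"amounts for {name!r} do not match the time grid")
            if np.any(a < 0):
                raise ValueError(f"amounts for {name!r} must be >= 0")
            amounts[name] = a
        object.__setattr__(self, "amounts", amounts)
        g = np.asarray(self.glucose_g_per_l, dtype=float)
        if g.shape != t.shape or np.any(g < 0):
            raise ValueError("glucose must match the time grid and be >= 0")
        object.__setattr__(self, "glucose_g_per_l", g)

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.amounts)


@dataclass(frozen=True)
class EnhancementResult:
    """Enhancement factor of one metabolite at one time and condition."""

    metabolite: str
    time_h: float
    talc_g_per_l: float
    ef: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None


@dataclass(frozen=True)
class UptakeProfile:
    """Volumetric glucose uptake rate along a time grid, plus its spline."""

    talc_g_per_l: float
    grid_h: np.ndarray
    rate_g_per_l_h: np.ndarray
    spline: BSpline

    def consumed(self) -> float:
        """Total glucose consumed over the spline domain (g L⁻¹)."""
        t0, t1 = self.spline.t[self.spline.k], self.spline.t[-self.spline.k - 1]
        return float(self.spline(t0) - self.spline(t1))


def enhancement_factor(
    treatment_amounts: Sequence[float],
    control_amounts: Sequence[float],
    alpha: float = 0.05,
    metabolite: str = "",
    time_h: float = float("nan"),
    talc_g_per_l: float = float("nan"),
) -> EnhancementResult:
    """EF = mean(treatment) / mean(control) with band and Welch p-value.

    The band comes from the delta method on log EF,
    ``var(log EF) ≈ s_t²/(n_t·m_t²) + s_c²/(n_c·m_c²)``, with a
    Student-t quantile at min(n_t, n_c) − 1 degrees of freedom. With a
    single replicate on either side the point estimate is returned and
    band/p-value are unavailable.
    """
    t = np.asarray(treatment_amounts, dtype=float).ravel()
    c = np.asarray(control_amounts, dtype=float).ravel()
    if t.size < 1 or c.size < 1:
        raise ValueError("need at least one replicate on each side")
    m_c = c.mean()
    if m_c <= 0:
        raise ValueError("control mean must be positive")
    m_t = t.mean()
    ef = float(m_t / m_c)
    if t.size < 2 or c.size < 2 or m_t <= 0:
        return EnhancementResult(metabolite, time_h, talc_g_per_l, ef, None, None, None)
    var_log = t.var(ddof=1) / (t.size * m_t**2) + c.var(ddof=1) / (c.size * m_c**2)
    df = min(t.size, c.size) - 1
    q = _st.t.ppf(1 - alpha / 2, df)
    half = q * math.sqrt(var_log)
    p = t_test_p(t, c)
    return EnhancementResult(
        metabolite, time_h, talc_g_per_l, ef,
        ci_low=float(ef * math.exp(-half)), ci_high=float(ef * math.exp(half)),
        p_value=p,
    )


def enhancement_table(
    series: Iterable[CultureTimeSeries],
    control_condition: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """EF per (metabolite, time, condition) from a replicate collection.

    Times with a non-positive control mean (typically inoculation, before
    any product is formed in appreciable amount) would make EF undefined;
    they are skipped only if the control mean is exactly zero.
    """
    series = list(series)
    conditions = sorted({s.talc_g_per_l for s in series})
    if control_condition not in conditions:
        raise ValueError(f"no control series at talc = {control_condition} g/L")
    controls = [s for s in series if s.talc_g_per_l == control_condition]
    times = controls[0].times_h
    metabolites = controls[0].metabolites
    rows = []
    for cond in conditions:
        if cond == control_condition:
            continue
        treats = [s for s in series if s.talc_g_per_l == cond]
        for m in metabolites:
            for it, t in enumerate(times):
                c_amt = np.array([s.amounts[m][it] for s in controls])
                t_amt = np.array([s.amounts[m][it] for s in treats])
                if c_amt.mean() == 0:
                    continue
                r = enhancement_factor(
                    t_amt, c_amt, alpha=alpha,
                    metabolite=m, time_h=float(t), talc_g_per_l=cond,
                )
                rows.append(
                    {
                        "metabolite": m,
                        "time_h": r.time_h,
                        "talc_g_per_L": r.talc_g_per_l,
                        "EF": r.ef,
                        "EF_lo": r.ci_low,
                        "EF_hi": r.ci_high,
                        "p_value": r.p_value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["metabolite", "time_h", "talc_g_per_L", "EF", "EF_lo", "EF_hi", "p_value"],
    )


def fit_concentration_spline(
    times: Sequence[float],
    concentrations: Sequence[float],
    bc: Literal["not-a-knot", "natural"] = "not-a-knot",
    smoothing: float | None = None,
) -> BSpline:
    """Fit a cubic B-spline to a concentration curve.

    The default is an interpolating cubic spline through the per-time
    replicate means with knots at the data times. ``bc`` selects the end
    condition: ``"not-a-knot"`` (default; reproduces cubic polynomials
    exactly) or ``"natural"`` (zero end curvature). A positive
    ``smoothing`` weight switches to a least-squares smoothing B-spline
    for noisy data.

    Duplicate times must carry identical values (replicates are averaged
    upstream); conflicting duplicates raise.
    """
    t = np.asarray(times, dtype=float).ravel()
    c = np.asarray(concentrations, dtype=float).ravel()
    if t.shape != c.shape:
        raise ValueError("times and concentrations differ in length")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
        raise ValueError("times and concentrations must be finite")
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    uniq, inverse = np.unique(t, return_inverse=True)
    if uniq.size != t.size:
        for k in range(uniq.size):
            vals = c[inverse == k]
            if not np.allclose(vals, vals[0], rtol=0, atol=0):
                raise ValueError(
                    f"conflicting values at duplicate time {uniq[k]}; average replicates first"
                )
        keep = np.concatenate(([True], np.diff(t) > 0))
        t, c = t[keep], c[keep]
    if t.size < 4:
        raise ValueError("need at least 4 distinct time points for a cubic spline")
    if smoothing is not None and smoothing > 0:
        tck = splrep(t, c, k=3, s=float(smoothing))
        return BSpline(*tck)
    if bc == "natural":
        return make_interp_spline(t, c, k=3, bc_type="natural")
    return make_interp_spline(t, c, k=3)


def uptake_rate(
    spline: BSpline, grid: Sequence[float], talc_g_per_l: float = float("nan")
) -> UptakeProfile:
    """Evaluate the uptake rate −dc/dt on a grid inside the spline domain."""
    g = np.asarray(grid, dtype=float).ravel()
    t0, t1 = spline.t[spline.k], spline.t[-spline.k - 1]
    if g.size == 0 or g.min() < t0 - 1e-12 or g.max() > t1 + 1e-12:
        raise ValueError(f"grid must lie within the fitted domain [{t0}, {t1}]")
    rate = -spline.derivative(1)(g)
    return UptakeProfile(
        talc_g_per_l=talc_g_per_l, grid_h=g, rate_g_per_l_h=rate, spline=spline
    )


def glucose_uptake_profiles(
    series: Iterable[CultureTimeSeries],
    grid: Sequence[float] | None = None,
    bc: Literal["not-a-knot", "natural"] = "not-a-knot",
    smoothing: float | None = None,
) -> list[UptakeProfile]:
    """Per-condition uptake profiles from the replicate-mean glucose curves."""
    series = list(series)
    profiles = []
    for cond in sorted({s.talc_g_per_l for s in series}):
        reps = [s for s in series if s.talc_g_per_l == cond]
        times = reps[0].times_h
        means = np.mean([s.glucose_g_per_l for s in reps], axis=0)
        spline = fit_concentration_spline(times, means, bc=bc, smoothing=smoothing)
        g = times if grid is None else np.asarray(grid, dtype=float)
        profiles.append(uptake_rate(spline, g, talc_g_per_l=cond))
    return profiles


# ---------------------------------------------------------------------------
# CSV round-trip (tidy format: one row per condition x replicate x time)

def timeseries_to_frame(series: Iterable[CultureTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for it, t in enumerate(s.times_h):
            row = {
                "talc_g_per_L": s.talc_g_per_l,
                "replicate": s.replicate,
                "time_h": float(t),
            }
            for m in s.metabolites:
                row[m] = s.amounts[m][it]
            row["glucose_g_per_L"] = s.glucose_g_per_l[it]
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_timeseries(df: pd.DataFrame) -> list[CultureTimeSeries]:
    meta_cols = {"talc_g_per_L", "replicate", "time_h", "glucose_g_per_L"}
    metabolites = [c for c in df.columns if c not in meta_cols]
    out = []
    for (cond, rep), grp in df.groupby(["talc_g_per_L", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            CultureTimeSeries(
                talc_g_per_l=float(cond),
                replicate=int(rep),
                times_h=grp["time_h"].to_numpy(),
                amounts={m: grp[m].to_numpy() for m in metabolites},
                glucose_g_per_l=grp["glucose_g_per_L"].to_numpy(),
            )
        )
    return out
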