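"""Screening-level one-compartment oral exposure model (Bateman curve),
per-target Hill-effect aggregation across components (HSA / Bliss
independence), chrono-window %T>IC50 coverage, dose finding, and
bioavailability scenarios.

The model is a deliberate engineering approximation: a single "hepatic"
compartment with first-order absorption (Ka) and elimination (k = Cl/Vd),
C(t) = F*D*Ka / (Vd_tot*(Ka-k)) * (exp(-k t) - exp(-Ka t)) in uM with the
molar dose D = dose_mg / MW.  Combination coverage is never computed on
summed concentrations: per-target effects E = C/(IC50 + C) (Hill n = 1) are
aggregated across components (HSA = max, Bliss = 1 - prod(1-E)), and
%T>IC50 is the fraction of the window where the aggregated effect is at
least 0.5 - which reduces exactly to C > IC50 for a single compound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import load_packaged_table

EPSILON_KA_EQ_K = 1e-6


@dataclass(frozen=True)
class PKParameters:
    """One-compartment oral PK constants for one compound."""
    ka: float                    # absorption rate, 1/h
    cl: float                    # clearance, L/h/kg
    vd: float                    # distribution volume, L/kg
    f: float                     # oral bioavailability fraction
    mw: float                    # g/mol
    body_mass: float = 70.0      # kg
    dose_mg: float = 100.0

    def __post_init__(self):
        for name in ("ka", "cl", "vd", "mw", "body_mass", "dose_mg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.f <= 1):
            raise ValueError("F must be in (0, 1]")
        if abs(self.ka - self.k) < EPSILON_KA_EQ_K:
            warnings.warn("Ka equals k; perturbing Ka by epsilon")
            object.__setattr__(self, "ka", self.ka * (1 + 10 * EPSILON_KA_EQ_K))

    @property
    def k(self) -> float:
        """Elimination rate constant, 1/h."""
        return self.cl / self.vd

    @property
    def vd_total(self) -> float:
        return self.vd * self.body_mass

    @property
    def molar_dose_umol(self) -> float:
        return self.dose_mg / self.mw * 1000.0

    @property
    def tmax(self) -> float:
        return math.log(self.ka / self.k) / (self.ka - self.k)

    @property
    def cmax(self) -> float:
        return bateman_concentration(self, self.tmax)

    @property
    def auc_inf(self) -> float:
        """Analytic AUC(0->inf) = F*D/(Cl*body_mass), uM*h."""
        return self.f * self.molar_dose_umol / (self.cl * self.body_mass)


def derive_pk_parameters(mw: float, logp: float, tpsa: float | None = None,
                         overrides: dict | None = None,
                         default_ka: float = 0.8, default_cl: float = 0.1,
                         default_f: float = 1.0, body_mass: float = 70.0,
                         dose_mg: float = 100.0) -> PKParameters:
    """Resolve PK parameters for a compound.

    Vd follows the empirical relationship Vd = 0.6 + 0.02 * logP (L/kg);
    Ka, Cl, F come from the overrides row when present, else the screening
    defaults (Ka = 0.8 1/h, Cl = 0.1 L/h/kg).  A full per-compound override
    row takes precedence over every derived value.
    """
    if mw is None or not mw > 0:
        raise ValueError("MW required to derive PK parameters")
    params = {
        "ka": default_ka, "cl": default_cl,
        "vd": 0.6 + 0.02 * logp, "f": default_f, "mw": mw,
    }
    if overrides:
        for key in ("ka", "cl", "vd", "f", "mw"):
            v = overrides.get(key)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                params[key] = float(v)
    return PKParameters(body_mass=body_mass, dose_mg=dose_mg, **params)


def load_pk_overrides() -> dict[str, dict]:
    """Packaged per-compound PK override table (anchor actives)."""
    df = load_packaged_table("pk_overrides.csv")
    return {r["compound"]: r.drop("compound").to_dict()
            for _, r in df.iterrows()}


def bateman_concentration(params: PKParameters, t) -> np.ndarray | float:
    """Hepatic concentration (uM) at time t (h) after a single oral dose."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    ka, k = params.ka, params.k
    amp = params.f * params.molar_dose_umol * ka / (params.vd_total * (ka - k))
    c = amp * (np.exp(-k * t) - np.exp(-ka * t))
    return float(c) if c.ndim == 0 else c


@dataclass
class ExposureProfile:
    compound: str
    t: np.ndarray                # h, uniform grid
    c: np.ndarray                # uM
    params: PKParameters

    @property
    def cmax(self) -> float:
        return float(self.c.max())

    @property
    def tmax(self) -> float:
        return float(self.t[int(np.argmax(self.c))])

    def auc_trapezoid(self) -> float:
        return float(np.trapezoid(self.c, self.t))


def simulate_exposure(params: PKParameters, compound: str = "",
                      t_end: float = 24.0, dt: float = 0.02) -> ExposureProfile:
    t = np.arange(0.0, t_end + dt / 2, dt)
    return ExposureProfile(compound=compound, t=t,
                           c=bateman_concentration(params, t), params=params)


def hill_effect(c, ic50: float) -> np.ndarray | float:
    """Fractional target engagement E = C/(IC50 + C), Hill n = 1."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    e = c / (ic50 + c)
    return float(e) if e.ndim == 0 else e


def combine_effects(effects, mode: str = "bliss") -> np.ndarray | float:
    """Aggregate component effects: HSA = max, Bliss = 1 - prod(1 - E)."""
    if len(effects) == 0:
        return 0.0
    E = np.asarray(effects, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("effects must lie in [0, 1]")
    mode = mode.lower()
    if mode == "hsa":
        out = E.max(axis=0)
    elif mode == "bliss":
        out = 1.0 - np.prod(1.0 - E, axis=0)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class WindowSpec:
    """A chrono-window: its interval, priority targets with weights, and
    per-target IC50s (uM, default 1)."""
    name: str
    t0: float
    t1: float
    target_weights: dict[str, float]
    ic50: dict[str, float] = field(default_factory=dict)
    aggregation: str = "bliss"

    def __post_init__(self):
        if not (self.t1 > self.t0 >= 0):
            raise ValueError("need t1 > t0 >= 0")
        if not self.target_weights or any(w < 0 for w in self.target_weights.values()) \
                or sum(self.target_weights.values()) <= 0:
            raise ValueError("target weights must be >= 0 with positive sum")

    def ic50_of(self, target: str) -> float:
        return self.ic50.get(target, 1.0)


@dataclass
class CoverageResult:
    window: str
    per_target: dict[str, float]     # %T with aggregated effect >= 0.5
    aggregated: float                # weighted mean over window targets, %
    cmax_total: float                # uM, summed display concentration
    tmax_total: float                # h


def window_coverage(profiles: list[ExposureProfile],
                    window: WindowSpec) -> CoverageResult:
    """%T>IC50 via per-target effect aggregation (never summed
    concentrations).  Coverage per target is the fraction of [t0, t1] where
    the aggregated Hill effect is >= 0.5; the window figure is the
    target-weight-weighted mean.  The summed concentration curve is reported
    only for display (Cmax / tmax)."""
    if not profiles:
        raise ValueError("need at least one exposure profile")
    t = profiles[0].t
    for p in profiles[1:]:
        if p.t.shape != t.shape or not np.allclose(p.t, t):
            raise ValueError("profiles must share the time grid")
    in_window = (t >= window.t0) & (t <= window.t1)
    if in_window.sum() < 2:
        raise ValueError("time grid does not cover the window")
    per_target = {}
    for target, w in window.target_weights.items():
        ic50 = window.ic50_of(target)
        effects = [hill_effect(p.c, ic50) for p in profiles]
        agg = combine_effects(effects, window.aggregation)
        per_target[target] = 100.0 * float(np.mean(agg[in_window] >= 0.5))
    weights = np.array([window.target_weights[t_] for t_ in per_target])
    aggregated = float(np.average(list(per_target.values()), weights=weights))
    total = np.sum([p.c for p in profiles], axis=0)
    return CoverageResult(window=window.name, per_target=per_target,
                          aggregated=aggregated,
                          cmax_total=float(total.max()),
                          tmax_total=float(t[int(np.argmax(total))]))


def simulate_combination(components: list[tuple[PKParameters, str]],
                         window: WindowSpec, t_end: float = 24.0,
                         dt: float = 0.02) -> tuple[CoverageResult, list[ExposureProfile]]:
    """Independent Bateman curves per component, combined by per-target
    effect aggregation."""
    profiles = [simulate_exposure(p, name, t_end=t_end, dt=dt)
                for p, name in components]
    return window_coverage(profiles, window), profiles


def find_min_dose(params: PKParameters, window: WindowSpec,
                  coverage_target: float, dose_grid,
                  regulatory_cap_mg: float | None = None,
                  t_end: float = 24.0, dt: float = 0.02,
                  refine_mg: float = 1.0) -> dict:
    """Minimum simulated daily dose (MSD): the smallest dose on the grid
    whose aggregated window coverage meets ``coverage_target`` (%), refined
    by bisection to ``refine_mg`` resolution.  An unreachable target (within
    the regulatory cap, if any) is reported with the best coverage attained.
    """
    doses = sorted(float(d) for d in dose_grid)
    if regulatory_cap_mg is not None:
        doses = [d for d in doses if d <= regulatory_cap_mg]
        if not doses:
            raise ValueError("dose grid entirely above the regulatory cap")

    def coverage_at(dose):
        p = replace(params, dose_mg=dose)
        prof = simulate_exposure(p, t_end=t_end, dt=dt)
        return window_coverage([prof], window).aggregated

    best_dose, best_cov = None, -1.0
    prev = None
    for d in doses:
        cov = coverage_at(d)
        if cov > best_cov:
            best_cov = cov
        if cov >= coverage_target:
            best_dose = d
            break
        prev = d
    if best_dose is None:
        return {"achievable": False, "msd_mg": None,
                "best_coverage": best_cov, "coverage": best_cov}
    lo, hi = (prev, best_dose) if prev is not None else (None, best_dose)
    if lo is not None:
        while hi - lo > refine_mg:
            mid = 0.5 * (lo + hi)
            if coverage_at(mid) >= coverage_target:
                hi = mid
            else:
                lo = mid
    msd = hi
    return {"achievable": True, "msd_mg": msd,
            "coverage": coverage_at(msd), "best_coverage": best_cov}


def bioavailability_scenario(params: PKParameters, factor: float) -> PKParameters:
    """Rescale exposure through F (capped at 1 with a warning), e.g. the
    ~5.2x phytosome enhancement benchmark."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    f = params.f * factor
    if f > 1:
        warnings.warn(f"F scaled to {f:.3g} > 1; capping at 1")
        f = 1.0
    return replace(params, f=f)


def exposure_report(profiles: list[ExposureProfile],
                    coverage: CoverageResult) -> pd.DataFrame:
    """Long-form time-series table plus summary rows."""
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({"compound": p.compound, "t_h": p.t,
                                    "c_uM": p.c}))
    ts = pd.concat(frames, ignore_index=True)
    ts.attrs["summary"] = {
        "window": coverage.window,
        "aggregated_coverage_pct": coverage.aggregated,
        "cmax_total_uM": coverage.cmax_total,
        "tmax_total_h": coverage.tmax_total,
        **{f"coverage_{k}_pct": v for k, v in coverage.per_target.items()},
    }
    return ts
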