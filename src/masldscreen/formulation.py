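"""Formulation design: translate ranked hits and PBPK dose estimates into
chrono-window product specifications under regulatory, mass, and diversity
constraints.

Selection is a mixed-integer linear program over binary (candidate, dose
level) variables: maximize alpha*TA + beta*TA_weighted of the selected
components subject to a total portion-mass cap, window membership, at most
one member per structural and per MOA cluster, a minimum pairwise Tanimoto
distance, and per-compound regulatory dose limits.  The published
formulation calls this step linear programming; the one-per-cluster and
selection logic require binary variables, so it is solved exactly as a MILP
(HiGHS backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .config import load_packaged_table


@dataclass
class Candidate:
    compound_id: str
    window: str
    ta: int
    ta_weighted: float
    cluster_id: int
    moa_cluster_id: int
    msd_mg: float
    dose_levels: tuple = ()           # candidate doses (mg); default (msd,)
    regulatory_limit_mg: float | None = None
    fingerprint: np.ndarray | None = None
    coverage_pct: float | None = None

    def doses(self) -> tuple:
        return self.dose_levels if self.dose_levels else (self.msd_mg,)


@dataclass
class FormulationSpec:
    product: str
    window: str
    components: list = field(default_factory=list)   # (compound_id, dose_mg, role)
    coverage_pct: float | None = None
    objective: float = 0.0
    constraints: dict = field(default_factory=dict)
    feasible: bool = True

    @property
    def total_mass_mg(self) -> float:
        return sum(d for _, d, _ in self.components)


def regulatory_check(msd_mg: float, limit_mg: float | None,
                     missing_policy: str = "flag") -> tuple[str, float]:
    """MSD within the daily limit -> base role at MSD; above it -> adjuvant
    at the capped dose.  Missing limits are handled per config."""
    if limit_mg is None:
        if missing_policy == "exclude":
            return "excluded", 0.0
        return "base", msd_mg        # flagged upstream; dose unconstrained
    if msd_mg <= limit_mg:
        return "base", msd_mg
    return "adjuvant", limit_mg


def coverage_tolerance_check(coverage_pct: float,
                             primary: float = 70.0,
                             tolerated: float = 50.0) -> str:
    """>=70% meets the primary design threshold; 50-70% is tolerated with a
    justified enhancement strategy; below 50% fails."""
    if not (0 <= coverage_pct <= 100):
        raise ValueError("coverage must be in [0, 100]")
    if coverage_pct >= primary:
        return "meets_primary"
    if coverage_pct >= tolerated:
        return "tolerated_with_justification"
    return "fail"


def _pairwise_tanimoto(fp_a, fp_b) -> float:
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0


def optimize_portfolio(candidates: list[Candidate], window: str,
                       portion_cap_mg: float = 2000.0,
                       alpha: float = 1.0, beta: float = 1.0,
                       min_tanimoto_distance: float = 0.3,
                       missing_policy: str = "flag",
                       product_name: str | None = None) -> FormulationSpec:
    """Select components and doses for one chrono-window product.

    Infeasible instances return the best relaxation (mass and pairwise
    constraints dropped in that order) with the violated constraints
    reported in the spec's constraint flags.
    """
    pool = [c for c in candidates if c.window == window]
    name = product_name or f"product_{window}"
    if not pool:
        return FormulationSpec(product=name, window=window, feasible=False,
                               constraints={"window_ok": False})

    variables = []      # (candidate index, dose)
    for ci, cand in enumerate(pool):
        role, cap_dose = regulatory_check(cand.msd_mg, cand.regulatory_limit_mg,
                                          missing_policy)
        if role == "excluded":
            continue
        for dose in cand.doses():
            dose = min(dose, cap_dose) if role == "adjuvant" else dose
            if cand.regulatory_limit_mg is not None and dose > cand.regulatory_limit_mg:
                continue
            variables.append((ci, float(dose), role))
    if not variables:
        return FormulationSpec(product=name, window=window, feasible=False,
                               constraints={"regulatory_ok": False})

    nv = len(variables)
    obj = np.array([-(alpha * pool[ci].ta + beta * pool[ci].ta_weighted)
                    for ci, _, _ in variables])

    def build_constraints(include_mass=True, include_pairs=True):
        cons = []
        # at most one dose level per candidate
        for ci in {v[0] for v in variables}:
            row = np.array([1.0 if v[0] == ci else 0.0 for v in variables])
            cons.append(LinearConstraint(row, -np.inf, 1.0))
        # one per structural / MOA cluster
        for attr in ("cluster_id", "moa_cluster_id"):
            for value in {getattr(pool[v[0]], attr) for v in variables}:
                row = np.array([1.0 if getattr(pool[v[0]], attr) == value
                                else 0.0 for v in variables])
                if row.sum() > 1:
                    cons.append(LinearConstraint(row, -np.inf, 1.0))
        if include_mass:
            cons.append(LinearConstraint(
                np.array([v[1] for v in variables]), -np.inf, portion_cap_mg))
        if include_pairs:
            for i, j in combinations(range(len(pool)), 2):
                fa, fb = pool[i].fingerprint, pool[j].fingerprint
                if fa is None or fb is None:
                    continue
                if 1.0 - _pairwise_tanimoto(fa, fb) < min_tanimoto_distance:
                    row = np.array([1.0 if v[0] in (i, j) else 0.0
                                    for v in variables])
                    cons.append(LinearConstraint(row, -np.inf, 1.0))
        return cons

    relaxations = [
        {"include_mass": True, "include_pairs": True},
        {"include_mass": True, "include_pairs": False},
        {"include_mass": False, "include_pairs": False},
    ]
    res = None
    used = relaxations[0]
    for relax in relaxations:
        r = milp(c=obj, constraints=build_constraints(**relax),
                 integrality=np.ones(nv),
                 bounds=Bounds(0, 1))
        if r.success:
            res, used = r, relax
            break
    if res is None:
        return FormulationSpec(product=name, window=window, feasible=False,
                               constraints={"solver_ok": False})

    chosen = [variables[i] for i in np.flatnonzero(np.round(res.x) == 1)]
    components = [(pool[ci].compound_id, dose, role) for ci, dose, role in chosen]
    spec = FormulationSpec(
        product=name, window=window, components=components,
        objective=float(-res.fun),
        feasible=used == relaxations[0],
    )
    spec.constraints = audit_constraints(spec, pool, portion_cap_mg,
                                         min_tanimoto_distance)
    cov = [pool[ci].coverage_pct for ci, _, _ in chosen
           if pool[ci].coverage_pct is not None]
    if cov:
        spec.coverage_pct = float(np.mean(cov))
    return spec


def audit_constraints(spec: FormulationSpec, pool: list[Candidate],
                      portion_cap_mg: float,
                      min_tanimoto_distance: float) -> dict:
    """Recompute every constraint flag from the emitted components
    (self-consistency audit)."""
    by_id = {c.compound_id: c for c in pool}
    chosen = [by_id[cid] for cid, _, _ in spec.components]
    flags = {
        "mass_ok": spec.total_mass_mg <= portion_cap_mg,
        "window_ok": all(c.window == spec.window for c in chosen),
        "regulatory_ok": all(
            c.regulatory_limit_mg is None or dose <= c.regulatory_limit_mg
            for (cid, dose, _), c in zip(spec.components, chosen)),
        "cluster_rule_ok": (
            len({c.cluster_id for c in chosen}) == len(chosen)
            and len({c.moa_cluster_id for c in chosen}) == len(chosen)),
    }
    div_ok = True
    for a, b in combinations(chosen, 2):
        if a.fingerprint is None or b.fingerprint is None:
            continue
        if 1.0 - _pairwise_tanimoto(a.fingerprint, b.fingerprint) < min_tanimoto_distance:
            div_ok = False
    flags["diversity_ok"] = div_ok
    return flags


def enumerate_portfolio(candidates: list[Candidate], window: str,
                        portion_cap_mg: float = 2000.0,
                        alpha: float = 1.0, beta: float = 1.0,
                        min_tanimoto_distance: float = 0.3) -> tuple[float, tuple]:
    """Brute-force optimum over all feasible subsets (small pools only);
    independent check of the MILP."""
    pool = [c for c in candidates if c.window == window]
    best = (0.0, ())
    n = len(pool)
    for mask in range(1, 1 << n):
        subset = [pool[i] for i in range(n) if mask >> i & 1]
        if any(c.regulatory_limit_mg is not None
               and c.msd_mg > c.regulatory_limit_mg for c in subset):
            doses = [min(c.msd_mg, c.regulatory_limit_mg)
                     if c.regulatory_limit_mg is not None else c.msd_mg
                     for c in subset]
        else:
            doses = [c.msd_mg for c in subset]
        if sum(doses) > portion_cap_mg:
            continue
        if len({c.cluster_id for c in subset}) < len(subset):
            continue
        if len({c.moa_cluster_id for c in subset}) < len(subset):
            continue
        ok = True
        for a, b in combinations(subset, 2):
            if a.fingerprint is None or b.fingerprint is None:
                continue
            if 1.0 - _pairwise_tanimoto(a.fingerprint, b.fingerprint) < min_tanimoto_distance:
                ok = False
                break
        if not ok:
            continue
        value = sum(alpha * c.ta + beta * c.ta_weighted for c in subset)
        if value > best[0]:
            best = (value, tuple(c.compound_id for c in subset))
    return best


def technology_report(compounds, descriptor_lookup: dict | None = None) -> pd.DataFrame:
    """Static carrier / stability / sensory lookup rows for the requested
    components; unknown compounds get descriptor-only rows (no inference)."""
    table = load_packaged_table("technology_table.csv")
    known = {r.compound: r for r in table.itertuples(index=False)}
    rows = []
    for name in compounds:
        key = str(name).lower()
        if key in known:
            rows.append(known[key]._asdict())
        else:
            d = (descriptor_lookup or {}).get(name, {})
            rows.append({"form": "", "compound": name,
                         "mw": d.get("mw"), "logp": d.get("logp"),
                         "tpsa": d.get("tpsa"), "stability_risks": "",
                         "carrier": "", "flavor_profile": ""})
    return pd.DataFrame(rows)


def write_portfolio(specs: list[FormulationSpec], path,
                    config_hash: str = "") -> None:
    """portfolio.csv writer: product, window, component, dose_mg, role,
    coverage_pct, constraint flags."""
    rows = []
    for s in specs:
        for cid, dose, role in s.components:
            rows.append({
                "product": s.product, "window": s.window, "component": cid,
                "dose_mg": dose, "role": role,
                "coverage_pct": s.coverage_pct,
                **{k: s.constraints.get(k) for k in
                   ("mass_ok", "window_ok", "diversity_ok",
                    "regulatory_ok", "cluster_rule_ok")},
            })
    df = pd.DataFrame(rows, columns=[
        "product", "window", "component", "dose_mg", "role", "coverage_pct",
        "mass_ok", "window_ok", "diversity_ok", "regulatory_ok",
        "cluster_rule_ok"])
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
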