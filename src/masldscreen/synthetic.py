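"""Seeded generator of structure-bearing multi-target bioactivity datasets
and PK scenarios with known ground truth.

The generator emulates the shape of a curated multi-target screening
extract: a flavonoid-like library built from a fixed scaffold-core catalog
with substituent enumeration (so Bemis-Murcko splits are meaningful),
pseudo-timestamps in generation order (so time splits are meaningful),
class-imbalanced per-target activity driven by a planted logistic model on
true continuous descriptors, IC50s drawn lognormally around the 1 uM
threshold so the binarized label is active with exactly the planted
probability, replicate noise that exercises the 15% RSE censoring rule, and
a planted subset of multi-target actives for enrichment checks.

Ground truth (per-target true probabilities, planted labels, and the
multi-target flag) is returned alongside so every downstream stage can be
scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .features import compute_descriptors

# Flavonoid-like cores with two substituent slots.  Distinct ring systems so
# each template is its own Murcko scaffold.
_CORES = (
    "O=c1cc(-c2ccc({0})cc2)oc2cc({1})ccc12",        # flavone
    "O=c1c(-c2ccc({0})cc2)coc2cc({1})ccc12",        # isoflavone
    "O=C1CC(c2ccc({0})cc2)Oc2cc({1})ccc21",         # flavanone
    "{0}c1ccc(/C=C/C(=O)c2ccccc2{1})cc1",           # chalcone
    "O=c1ccc2cc({0})c({1})cc2o1",                   # coumarin
    "{0}c1ccc(-c2cc3cc({1})ccc3o2)cc1",             # 2-arylbenzofuran
    "O=C1/C(=C\\c2ccc({0})cc2)Oc2cc({1})ccc21",     # aurone
    "O=c1cc(-c2ccc({0})cc2)[nH]c2cc({1})ccc12",     # azaflavone
    "{0}c1ccc(-c2nc3cc({1})ccc3o2)cc1",             # benzoxazole
    "{0}c1ccc(/C=C/c2cc({1})cc(O)c2)cc1",           # stilbene
    "O=c1c2cc({0})ccc2oc2cc({1})ccc12",             # xanthone
    "{0}c1ccc(-c2csc3cc({1})ccc23)cc1",             # arylbenzothiophene
)

_SUBSTITUENTS = (
    "O", "OC", "C", "CC", "F", "Cl", "Br", "N", "C#N", "C(F)(F)F",
    "CO", "OCC", "C(C)C", "NC", "C(=O)O", "C(=O)N", "S", "SC", "CCO", "OC(C)C",
)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic screening dataset."""
    n_compounds: int = 600
    n_targets: int = 10
    n_scaffolds: int = 12
    prevalence: float = 0.30            # per-target active fraction
    signal_scale: float = 4.0           # latent logistic effect size
    ic50_sigma: float = 0.6             # lognormal spread, log10 units
    n_replicates: int = 3
    replicate_cv: float = 0.2           # exercises RSE censoring
    multi_target_fraction: float = 0.08
    multi_target_boost: float = 2.5     # latent boost on the planted subset
    seed: int = 0

    target_ids: tuple = field(default=None)

    def __post_init__(self):
        if self.target_ids is None:
            from .config import TargetPanel
            panel = TargetPanel.default()
            if self.n_targets == len(panel.target_ids):
                self.target_ids = panel.target_ids
            else:
                self.target_ids = tuple(f"T{i:02d}" for i in range(self.n_targets))


def generate_library(spec: SyntheticSpec) -> pd.DataFrame:
    """Enumerate a valid, seed-deterministic SMILES library with scaffold
    labels and pseudo-timestamps (generation order)."""
    from rdkit import Chem

    rng = np.random.default_rng(spec.seed)
    n_cores = min(spec.n_scaffolds, len(_CORES))
    rows = []
    seen = set()
    i = 0
    max_attempts = 200 * spec.n_compounds
    while len(rows) < spec.n_compounds:
        if i >= max_attempts:
            raise ValueError(
                f"could not enumerate {spec.n_compounds} unique structures "
                f"from {n_cores} cores; reduce n_compounds")
        core_idx = i % n_cores if len(rows) < n_cores * 2 else int(rng.integers(n_cores))
        subs = rng.choice(len(_SUBSTITUENTS), size=2, replace=True)
        smi = _CORES[core_idx].format(_SUBSTITUENTS[subs[0]],
                                      _SUBSTITUENTS[subs[1]])
        i += 1
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        rows.append({"compound_ref": f"SYN{len(rows):05d}", "smiles": canonical,
                     "scaffold_core": core_idx, "timestamp": len(rows)})
    return pd.DataFrame(rows)


def _planted_probabilities(library: pd.DataFrame, spec: SyntheticSpec,
                           rng) -> tuple[np.ndarray, np.ndarray]:
    """Latent logistic model on standardized true descriptors; intercepts
    solved per target so the mean probability matches the configured
    prevalence.  Returns (p true, multi-target mask)."""
    desc = pd.DataFrame([compute_descriptors(s) for s in library["smiles"]])
    X = desc.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    n, d = X.shape
    multi = rng.random(n) < spec.multi_target_fraction
    P = np.empty((n, spec.n_targets))
    for t in range(spec.n_targets):
        w = rng.normal(0, 1, size=d)
        z = X @ w
        z = spec.signal_scale * z / max(z.std(), 1e-9)
        z = z + multi * spec.multi_target_boost
        # intercept via bisection so mean(sigmoid(z + b)) = prevalence
        lo, hi = -30.0, 30.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if expit(z + mid).mean() > spec.prevalence:
                hi = mid
            else:
                lo = mid
        P[:, t] = expit(z + 0.5 * (lo + hi))
    return P, multi


def generate_bioactivities(library: pd.DataFrame, spec: SyntheticSpec
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bioactivity record table (the curation-module input dialect) plus the
    ground-truth sidecar.

    Per compound and target the latent activity probability p is realized
    through the IC50 draw itself: log10 IC50_nM = 3 - sigma * (z + g),
    z = Phi^{-1}(p), g ~ N(0,1), so P(IC50 <= 1000 nM) = p exactly.
    Replicates multiply in lognormal noise at the configured CV.
    """
    rng = np.random.default_rng(spec.seed + 1)
    P, multi = _planted_probabilities(library, spec, rng)

    records = []
    truth_rows = []
    log_sd = np.sqrt(np.log1p(spec.replicate_cv ** 2))
    for i, row in enumerate(library.itertuples(index=False)):
        for t, target in enumerate(spec.target_ids):
            p = float(np.clip(P[i, t], 1e-9, 1 - 1e-9))
            z = norm.ppf(p) + rng.normal()
            log10_ic50 = 3.0 - spec.ic50_sigma * z
            center = 10.0 ** np.clip(log10_ic50, -3.0, 9.0)
            noise = rng.lognormal(mean=-0.5 * log_sd ** 2, sigma=log_sd,
                                  size=spec.n_replicates)
            for r in range(spec.n_replicates):
                records.append({
                    "compound_ref": row.compound_ref,
                    "smiles": row.smiles,
                    "target_id": target,
                    "ic50_nM": center * noise[r],
                    "replicate_group": f"{row.compound_ref}:{target}",
                    "timestamp": row.timestamp,
                })
            truth_rows.append({
                "compound_ref": row.compound_ref, "target_id": target,
                "true_p": p, "center_ic50_nM": center,
                "true_label": int(center <= 1000.0),
                "is_multi_target": bool(multi[i]),
            })
    return pd.DataFrame(records), pd.DataFrame(truth_rows)


def generate_dataset(spec: SyntheticSpec) -> dict:
    """Library + records + ground truth in one call."""
    library = generate_library(spec)
    records, truth = generate_bioactivities(library, spec)
    return {"library": library, "records": records, "truth": truth,
            "spec": spec}


REFERENCE_DEFAULT_SCENARIO = {
    "name": "reference_defaults",
    "ka": 0.8, "cl": 0.1, "logp": 2.0, "vd": 0.6 + 0.02 * 2.0, "f": 1.0,
}

_PK_BOUNDS = {"ka": (0.2, 2.0), "cl": (0.02, 0.5), "f": (0.05, 1.0)}


def generate_pk_scenarios(n: int, seed: int = 0) -> pd.DataFrame:
    """Physiologically bounded random PK parameter sets plus the named
    default scenario (Ka = 0.8 1/h, Cl = 0.1 L/h/kg, Vd from logP)."""
    rng = np.random.default_rng(seed)
    rows = [dict(REFERENCE_DEFAULT_SCENARIO)]
    for i in range(n):
        logp = float(rng.uniform(0.5, 4.0))
        rows.append({
            "name": f"scenario_{i:03d}",
            "ka": float(rng.uniform(*_PK_BOUNDS["ka"])),
            "cl": float(rng.uniform(*_PK_BOUNDS["cl"])),
            "logp": logp,
            "vd": 0.6 + 0.02 * logp,
            "f": float(rng.uniform(*_PK_BOUNDS["f"])),
        })
    return pd.DataFrame(rows)
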