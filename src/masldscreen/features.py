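"""Molecular features: Morgan bit fingerprints, continuous physicochemical
descriptors, and the feature-curation rules (near-zero-variance removal,
mutual-information-guided decorrelation, robust scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from sklearn.metrics import mutual_info_score

from .config import load_packaged_table

FP_RADIUS = 2
FP_BITS = 2048

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br")

CONTINUOUS_NAMES = (
    "mw", "hbd", "hba", "logp", "tpsa", "rotatable_bonds",
) + tuple(f"n_{el}" for el in _ELEMENTS)

_fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


def _as_mol(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"invalid structure: {structure!r}")
    return mol


def compute_fingerprint(structure) -> np.ndarray:
    """Extended-connectivity (Morgan) fingerprint, radius 2, 2048 bits."""
    fp = _fpgen.GetFingerprint(_as_mol(structure))
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def load_descriptor_overrides() -> dict[str, dict]:
    """Packaged fallback descriptor set (anchor actives): MW, logP, TPSA."""
    df = load_packaged_table("descriptor_overrides.csv")
    return {
        r.compound: {"mw": r.mw, "logp": r.logp, "tpsa": r.tpsa}
        for r in df.itertuples(index=False)
    }


def compute_descriptors(structure, compound_name: str | None = None,
                        overrides: dict[str, dict] | None = None) -> dict[str, float]:
    """Continuous descriptors; named overrides (MW/logP/TPSA) take precedence
    over computed values when present."""
    mol = _as_mol(structure)
    d = {
        "mw": Descriptors.MolWt(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "logp": Crippen.MolLogP(mol),
        "tpsa": Descriptors.TPSA(mol),
        "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
    }
    counts = {el: 0 for el in _ELEMENTS}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
    h_total = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    for el in _ELEMENTS:
        d[f"n_{el}"] = counts[el]
    d["n_H"] = h_total
    if overrides and compound_name and compound_name in overrides:
        d.update(overrides[compound_name])
    return d


@dataclass
class FeatureMatrix:
    """Compound-indexed feature block: binary Morgan bits + continuous
    descriptors, with the retained-feature list and robust-scaler parameters
    learned on the training fold and reused downstream."""

    index: pd.Index
    bits: np.ndarray                  # (n, <=2048) uint8
    continuous: pd.DataFrame          # (n, n_cont)
    retained_bits: np.ndarray = field(default=None)
    retained_continuous: list = field(default=None)
    scaler_params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.index)

    def matrix(self) -> np.ndarray:
        """Curated design matrix (bits then scaled continuous)."""
        blocks = []
        bits = self.bits if self.retained_bits is None else self.bits[:, self.retained_bits]
        blocks.append(bits.astype(np.float32))
        cont = self.continuous if self.retained_continuous is None \
            else self.continuous[self.retained_continuous]
        arr = cont.to_numpy(dtype=float)
        for j, name in enumerate(cont.columns):
            p = self.scaler_params.get(name)
            if p is not None:
                arr[:, j] = (arr[:, j] - p["center"]) / p["scale"]
        blocks.append(arr.astype(np.float32))
        return np.hstack(blocks)


def featurize(smiles_list, index=None, names=None, overrides=None) -> FeatureMatrix:
    index = pd.Index(index if index is not None else range(len(smiles_list)))
    bits = np.vstack([compute_fingerprint(s) for s in smiles_list])
    rows = []
    for i, s in enumerate(smiles_list):
        name = names[i] if names is not None else None
        rows.append(compute_descriptors(s, name, overrides))
    cont = pd.DataFrame(rows, index=index)
    return FeatureMatrix(index=index, bits=bits, continuous=cont)


def _binned_mi(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Mutual information with the label after equal-frequency binning."""
    if np.unique(x).size <= bins:
        codes = pd.factorize(x)[0]
    else:
        codes = pd.qcut(x, q=bins, labels=False, duplicates="drop")
    return mutual_info_score(codes, y)


def curate_features(fm: FeatureMatrix, labels,
                    min_bit_frequency: float = 0.01,
                    min_variance: float = 1e-8,
                    corr_limit: float = 0.95) -> FeatureMatrix:
    """Apply the feature-curation rules on a training set.

    1. Drop near-zero-variance features: bits with minority frequency below
       ``min_bit_frequency``; continuous features with variance below
       ``min_variance``.
    2. For continuous pairs with |r| > ``corr_limit``, keep the member with
       higher mutual information with the activity label.
    3. Robust-scale the continuous block: (x - median) / IQR, with MAD then
       no-op fallback for zero-IQR features.

    The retained-feature lists and scaler parameters are stored on the
    returned matrix and must be reused for validation/test compounds.
    """
    y = np.asarray(labels)
    freq = fm.bits.mean(axis=0)
    minority = np.minimum(freq, 1 - freq)
    retained_bits = np.flatnonzero(minority >= min_bit_frequency)

    cont = fm.continuous
    keep = [c for c in cont.columns if cont[c].to_numpy(dtype=float).var() >= min_variance]
    cont = cont[keep]

    if len(cont.columns) > 1:
        corr = cont.corr().abs().to_numpy()
        mi = {c: _binned_mi(cont[c].to_numpy(dtype=float), y) for c in cont.columns}
        cols = list(cont.columns)
        dropped = set()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if cols[i] in dropped or cols[j] in dropped:
                    continue
                if corr[i, j] > corr_limit:
                    loser = cols[i] if mi[cols[i]] < mi[cols[j]] else cols[j]
                    dropped.add(loser)
        keep = [c for c in cols if c not in dropped]

    if retained_bits.size == 0 and not keep:
        raise ValueError("feature curation removed every feature")

    scaler = {}
    for c in keep:
        x = fm.continuous[c].to_numpy(dtype=float)
        med = float(np.median(x))
        q75, q25 = np.percentile(x, [75, 25])  # linear interpolation
        iqr = float(q75 - q25)
        if iqr > 0:
            scaler[c] = {"center": med, "scale": iqr}
        else:
            mad = float(np.median(np.abs(x - med)))
            scaler[c] = {"center": med, "scale": mad} if mad > 0 \
                else {"center": 0.0, "scale": 1.0}

    return FeatureMatrix(index=fm.index, bits=fm.bits, continuous=fm.continuous,
                         retained_bits=retained_bits,
                         retained_continuous=keep, scaler_params=scaler)


def apply_curation(fm: FeatureMatrix, fitted: FeatureMatrix) -> FeatureMatrix:
    """Carry a fitted curation (retained features + scaler) to new compounds."""
    return FeatureMatrix(index=fm.index, bits=fm.bits, continuous=fm.continuous,
                         retained_bits=fitted.retained_bits,
                         retained_continuous=fitted.retained_continuous,
                         scaler_params=fitted.scaler_params)
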