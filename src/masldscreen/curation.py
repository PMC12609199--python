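"""Bioactivity curation: structure standardization, deduplication, replicate
aggregation, activity binarization, RSE censoring, and regulatory triage.

The curation contract mirrors the screening protocol: canonical SMILES +
InChIKey, counter-ion removal (largest organic fragment), canonical tautomer,
a fixed pH-7.4 protonation rule set, replicate IC50s aggregated by the
median, a 1 uM activity threshold, and censoring of labels whose relative
standard error exceeds 15%.  Every input record is accounted for: merged into
a curated compound or rejected with a logged reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import inchi
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

REQUIRED_COLUMNS = ("compound_ref", "smiles", "target_id", "ic50_nM",
                    "replicate_group", "timestamp")

# pH 7.4 protonation rules (fixed, config-documented): carboxylic and sulfonic
# acids are deprotonated (pKa well below 7.4); aliphatic (non-aromatic,
# non-amide) amines are protonated (pKa above 7.4).  Applied after neutral
# canonical-tautomer assignment so re-standardization is idempotent.
_ACID_SMARTS = (
    Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1]"),
)
_AMINE_SMARTS = Chem.MolFromSmarts(
    "[NX3;H2,H1,H0;!$(NC=[O,S,N]);!$(Na);!$(N=*);!$(N-[O,N]);!a]"
)


@dataclass
class StandardizedStructure:
    canonical_smiles: str
    inchikey: str
    tautomer_signature: str

    @property
    def inchikey_block(self) -> str:
        """First (14-char connectivity) block, the deduplication key."""
        return self.inchikey.split("-")[0]


@dataclass
class CuratedCompound:
    compound_id: str
    canonical_smiles: str
    inchikey: str
    tautomer_signature: str
    # per target: median_ic50_nM, n_replicates, rse, label
    per_target: dict[str, dict] = field(default_factory=dict)
    status: str = "experimental_gap"
    member_refs: tuple = ()


def _neutral_canonical(mol: Chem.Mol) -> Chem.Mol:
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.LargestFragmentChooser(preferOrganic=True).choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    enumerator = rdMolStandardize.TautomerEnumerator()
    return enumerator.Canonicalize(mol)


def _apply_ph74(mol: Chem.Mol) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for pattern in _ACID_SMARTS:
        for match in mol.GetSubstructMatches(pattern):
            oxygen = rw.GetAtomWithIdx(match[-1])
            if oxygen.GetFormalCharge() == 0 and oxygen.GetTotalNumHs() == 1:
                oxygen.SetFormalCharge(-1)
                oxygen.SetNumExplicitHs(0)
                oxygen.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    rw = Chem.RWMol(mol)
    for match in mol.GetSubstructMatches(_AMINE_SMARTS):
        atom = rw.GetAtomWithIdx(match[0])
        if atom.GetFormalCharge() == 0:
            atom.SetFormalCharge(1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            atom.SetNoImplicit(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def standardize_structure(smiles: str, ph74_rules: bool = True) -> StandardizedStructure:
    """Standardize a structure: largest organic fragment, canonical tautomer,
    fixed pH-7.4 protonation, canonical SMILES + InChIKey.

    Idempotent: standardizing the output reproduces the output.  The tautomer
    signature is the InChIKey of the neutral canonical tautomer, so tautomer
    drawings of the same compound collapse to one signature.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    neutral = _neutral_canonical(mol)
    signature = inchi.MolToInchiKey(neutral)
    final = _apply_ph74(neutral) if ph74_rules else neutral
    return StandardizedStructure(
        canonical_smiles=Chem.MolToSmiles(final),
        inchikey=inchi.MolToInchiKey(final),
        tautomer_signature=signature,
    )


def binarize_activity(median_ic50_nM: float, threshold_nM: float = 1000.0) -> str:
    """Active iff median IC50 <= threshold (1 uM boundary inclusive)."""
    if threshold_nM <= 0:
        raise ValueError("threshold must be positive")
    if median_ic50_nM <= 0:
        raise ValueError("IC50 must be positive")
    return "active" if median_ic50_nM <= threshold_nM else "inactive"


def replicate_rse(values) -> float:
    """Relative standard error of the mean over replicate IC50s.

    RSE = SEM / mean; a single measurement has no internal inconsistency and
    returns 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size <= 1:
        return 0.0
    sem = v.std(ddof=1) / math.sqrt(v.size)
    return float(sem / v.mean())


def censor_by_rse(rse: float, rse_threshold: float = 0.15) -> str:
    """Censor a label when the RSE strictly exceeds the threshold."""
    if rse < 0:
        raise ValueError("rse must be >= 0")
    return "censor" if rse > rse_threshold else "keep"


def _load_registry(name: str, override: str | Path | None = None) -> set[str]:
    if override is not None:
        p = Path(override)
        if not p.exists():
            raise FileNotFoundError(
                f"registry file {p} not found; omit the override to use the "
                "packaged default lists"
            )
        text = p.read_text()
    else:
        text = resources.files("masldscreen.data").joinpath(name).read_text()
    keys = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        keys.add(line.split()[0][:14])
    return keys


def assign_regulatory_status(
    inchikey: str,
    food_grade_path: str | Path | None = None,
    red_flag_path: str | Path | None = None,
) -> str:
    """food_grade if listed in the GRAS/Novel-Food list, red_flag if in the
    toxicology-alert list, else experimental_gap.  Membership is by the
    14-character InChIKey connectivity block."""
    block = inchikey.split("-")[0][:14]
    if block in _load_registry("registry_red_flag.txt", red_flag_path):
        return "red_flag"
    if block in _load_registry("registry_food_grade.txt", food_grade_path):
        return "food_grade"
    return "experimental_gap"


def deduplicate_and_aggregate(
    records: pd.DataFrame,
    activity_threshold_nM: float = 1000.0,
    rse_threshold: float = 0.15,
    panel_targets=None,
    ph74_rules: bool = True,
) -> tuple[list[CuratedCompound], pd.DataFrame]:
    """Standardize, deduplicate on (first InChIKey block, tautomer signature),
    aggregate replicate IC50s by the median, binarize, and censor.

    Returns (curated compounds, rejection log).  The rejection log carries one
    row per dropped record with its reason, so input records are conserved
    across kept/merged/censored/rejected outcomes.
    """
    rejects = []
    std_cache: dict[str, StandardizedStructure | None] = {}
    rows = []
    for rec in records.itertuples(index=False):
        smi = rec.smiles
        if smi not in std_cache:
            try:
                std_cache[smi] = standardize_structure(smi, ph74_rules=ph74_rules)
            except ValueError as exc:
                std_cache[smi] = None
                log.warning("rejected structure %r: %s", smi, exc)
        std = std_cache[smi]
        ic50 = float(rec.ic50_nM)
        if std is None:
            rejects.append({"compound_ref": rec.compound_ref, "smiles": smi,
                            "reason": "unparseable structure"})
            continue
        if not ic50 > 0:
            rejects.append({"compound_ref": rec.compound_ref, "smiles": smi,
                            "reason": "non-positive IC50"})
            continue
        if panel_targets is not None and rec.target_id not in panel_targets:
            rejects.append({"compound_ref": rec.compound_ref, "smiles": smi,
                            "reason": f"target {rec.target_id} not in panel"})
            continue
        rows.append({
            "key": (std.inchikey_block, std.tautomer_signature),
            "std": std, "ref": rec.compound_ref,
            "target_id": rec.target_id, "ic50_nM": ic50,
        })

    compounds: dict[tuple, CuratedCompound] = {}
    for row in sorted(rows, key=lambda r: str(r["ref"])):
        key = row["key"]
        if key not in compounds:
            std = row["std"]
            compounds[key] = CuratedCompound(
                compound_id=str(row["ref"]),
                canonical_smiles=std.canonical_smiles,
                inchikey=std.inchikey,
                tautomer_signature=std.tautomer_signature,
            )
        comp = compounds[key]
        comp.member_refs = tuple(sorted(set(comp.member_refs) | {str(row["ref"])}))
        comp.per_target.setdefault(row["target_id"], {"values": []})
        comp.per_target[row["target_id"]]["values"].append(row["ic50_nM"])

    for comp in compounds.values():
        for target, cell in comp.per_target.items():
            values = cell.pop("values")
            median = float(np.median(values))
            rse = replicate_rse(values)
            label = binarize_activity(median, activity_threshold_nM)
            if censor_by_rse(rse, rse_threshold) == "censor":
                label = "censored"
            cell.update(median_ic50_nM=median, n_replicates=len(values),
                        rse=rse, label=label)
        comp.status = assign_regulatory_status(comp.inchikey)

    return list(compounds.values()), pd.DataFrame(
        rejects, columns=["compound_ref", "smiles", "reason"])


def curated_table(compounds: list[CuratedCompound]) -> pd.DataFrame:
    """Long-form curated table: one row per compound x target."""
    rows = []
    for c in compounds:
        for target, cell in sorted(c.per_target.items()):
            rows.append({
                "compound_id": c.compound_id,
                "canonical_smiles": c.canonical_smiles,
                "inchikey": c.inchikey,
                "target_id": target,
                "median_ic50_nM": cell["median_ic50_nM"],
                "n_replicates": cell["n_replicates"],
                "rse": cell["rse"],
                "label": cell["label"],
                "status": c.status,
            })
    return pd.DataFrame(rows)


def read_bioactivity_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bioactivity table missing columns: {missing}")
    return df


def read_bioactivity_sdf(path: str | Path) -> pd.DataFrame:
    """SDF input: one record per molecule, fields as SD properties."""
    rows = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        rows.append({
            "compound_ref": props.get("compound_ref", mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
            "smiles": Chem.MolToSmiles(mol),
            "target_id": props.get("target_id"),
            "ic50_nM": props.get("ic50_nM"),
            "replicate_group": props.get("replicate_group", ""),
            "timestamp": props.get("timestamp", 0),
        })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
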