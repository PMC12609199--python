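"""Standardize structures and curate a small bioactivity table.

Builds a handful of raw records (salts, replicates, a noisy triplicate, an
unparseable entry), then runs the curation contract: largest-fragment salt
stripping, canonical tautomers, pH-7.4 protonation, median aggregation over
replicates, the 1 uM activity threshold, 15% RSE censoring, and regulatory
triage against the packaged food-grade / alert lists.
"""

import pandas as pd

from masldscreen import deduplicate_and_aggregate, standardize_structure
from masldscreen.curation import curated_table

records = pd.DataFrame([
    # genistein free acid and its (hypothetical) sodium salt: one compound
    {"compound_ref": "genistein", "smiles": "c1cc(ccc1-c1coc2cc(O)cc(O)c2c1=O)O",
     "target_id": "LIPG", "ic50_nM": 400.0},
    {"compound_ref": "genistein_na", "smiles": "c1cc(ccc1-c1coc2cc(O)cc(O)c2c1=O)O.[Na+]",
     "target_id": "LIPG", "ic50_nM": 600.0},
    # a reproducible triplicate (active at the 1 uM threshold)
    *({"compound_ref": "naringenin", "smiles": "O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21",
       "target_id": "FABP4", "ic50_nM": v} for v in (800.0, 900.0, 1000.0)),
    # a wildly inconsistent triplicate -> censored by the RSE rule
    *({"compound_ref": "noisy", "smiles": "Oc1ccc(CCN)cc1",
       "target_id": "FABP4", "ic50_nM": v} for v in (50.0, 800.0, 9000.0)),
    {"compound_ref": "broken", "smiles": "xx-not-a-structure",
     "target_id": "LIPG", "ic50_nM": 10.0},
])
records["replicate_group"] = records["compound_ref"]
records["timestamp"] = 0

std = standardize_structure("c1cc(ccc1-c1coc2cc(O)cc(O)c2c1=O)O.[Na+]")
print("salt-stripped canonical SMILES:", std.canonical_smiles)
print("InChIKey:", std.inchikey, "\n")

compounds, rejects = deduplicate_and_aggregate(records)
print(curated_table(compounds).to_string(index=False))
print("\nrejected records:")
print(rejects.to_string(index=False))

# The genistein rows merge on the InChIKey connectivity block (median IC50
# 500 nM, food_grade) but their two-point spread gives RSE = 20% > 15%, so
# the label is censored rather than trusted; the reproducible naringenin
# triplicate stays active; the unparseable entry lands in the rejection log.
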