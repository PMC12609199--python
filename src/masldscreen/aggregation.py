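"""System-level aggregation of calibrated per-target probabilities.

Total activity (TA) counts the targets whose calibrated p(active) meets the
uniform 0.50 threshold; TA_weighted is the pathway-weighted sum of
probabilities (Table-2-style weights by default, mean weighting when no
weights are configured).  Candidates are ranked hierarchically (TA, then the
main weighted score, TA_weighted as tie-breaker), tiered by priority, and
inter-model rank concordance is quantified with Kendall's W and top-N
Jaccard overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import TargetPanel


def total_activity(p, threshold: float = 0.50, inclusive: bool = True) -> int:
    """Number of targets whose p(active) meets the per-target threshold."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities outside [0, 1]")
    return int(np.sum(p >= threshold if inclusive else p > threshold))


def weighted_total_activity(p, panel: TargetPanel | None = None,
                            weights=None) -> float:
    """Sum_t w_t * p_t; with no weights configured the mean-weighted sum."""
    p = np.asarray(p, dtype=float)
    if weights is None and panel is not None:
        weights = panel.weight_vector
    if weights is None:
        weights = np.full(p.size, 1.0 / p.size)
    weights = np.asarray(weights, dtype=float)
    if weights.size != p.size:
        raise ValueError(f"length mismatch: {p.size} probabilities vs "
                         f"{weights.size} weights")
    return float(np.dot(weights, p))


def assign_priority(ta: int) -> str:
    """TA >= 3 high, TA 1-2 medium, TA 0 low."""
    if ta < 0 or int(ta) != ta:
        raise ValueError("TA must be a non-negative integer")
    if ta >= 3:
        return "high"
    if ta >= 1:
        return "medium"
    return "low"


def selectivity_flag(p, max_threshold: float = 0.80,
                     second_threshold: float = 0.40) -> bool:
    """Narrow-profile marker: top probability >= 0.80 and runner-up <= 0.40."""
    p = np.sort(np.asarray(p, dtype=float))[::-1]
    if p.size < 2:
        raise ValueError("need at least two targets")
    return bool(p[0] >= max_threshold and p[1] <= second_threshold)


def selectivity_entropy(p, base: str = "natural") -> float:
    """Shannon entropy of the probability profile normalized to a
    distribution; low entropy = specialization, high = multi-target."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        warnings.warn("all-zero profile; entropy defined as 0")
        return 0.0
    q = p / total
    q = q[q > 0]
    h = float(-(q * np.log(q)).sum())
    if base == "bits":
        h /= np.log(2)
    return h


def rank_candidates(hits: pd.DataFrame) -> pd.DataFrame:
    """Order descending by TA, then main_score, then TA_weighted; stable for
    full ties (input order preserved)."""
    return hits.sort_values(
        by=["TA", "main_score", "TA_weighted"],
        ascending=[False, False, False], kind="stable")


def kendalls_w(rank_matrix) -> float:
    """Kendall's coefficient of concordance over m judges x n items with tie
    correction: W = 12S / (m^2(n^3-n) - m*sum_T)."""
    R = np.asarray(rank_matrix, dtype=float)
    m, n = R.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 judges and 2 items")
    ranks = np.vstack([rankdata(row) for row in R])
    totals = ranks.sum(axis=0)
    s = float(np.sum((totals - totals.mean()) ** 2))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = m ** 2 * (n ** 3 - n) - m * tie_term
    if denom <= 0:
        return 1.0 if s == 0 else 0.0
    return float(12.0 * s / denom)


def topn_jaccard(lists, n: int = 20) -> float:
    """Mean pairwise Jaccard index over per-model top-N id sets."""
    if n < 1:
        raise ValueError("N must be >= 1")
    sets = [set(list(lst)[:n]) for lst in lists]
    if len(sets) < 2:
        raise ValueError("need at least two lists")
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = sets[i] | sets[j]
            vals.append(len(sets[i] & sets[j]) / len(union) if union else 1.0)
    return float(np.mean(vals))


def score_hits(prob_matrix: pd.DataFrame, panel: TargetPanel,
               smiles: dict | None = None,
               threshold: float = 0.50, inclusive: bool = True,
               main_score=None) -> pd.DataFrame:
    """Assemble the ranked-hit table from a compound x target probability
    matrix.  main_score defaults to TA_weighted when no separate weighted
    score is configured."""
    cols = list(panel.target_ids)
    P = prob_matrix[cols].to_numpy(dtype=float)
    ta = np.array([total_activity(row, threshold, inclusive) for row in P])
    taw = np.array([weighted_total_activity(row, panel) for row in P])
    hits = pd.DataFrame({
        "compound_id": prob_matrix.index,
        "TA": ta,
        "TA_weighted": taw,
        "main_score": taw if main_score is None else np.asarray(main_score),
        "priority": [assign_priority(t) for t in ta],
        "entropy": [selectivity_entropy(row) if row.sum() > 0 else 0.0
                    for row in P],
        "selectivity_flag": [selectivity_flag(row) for row in P],
    })
    if smiles is not None:
        hits.insert(1, "smiles", [smiles.get(c, "") for c in hits["compound_id"]])
    for t in cols:
        hits[f"p_{t}"] = prob_matrix[t].to_numpy()
    return rank_candidates(hits).reset_index(drop=True)


def read_artifact_csv(path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the optional leading config-hash line.

    (A plain ``comment='#'`` parse would truncate SMILES containing '#'.)
    """
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("#") else 0
    return pd.read_csv(path, skiprows=skip, **kwargs)


def write_ranked_hits(hits: pd.DataFrame, path, config_hash: str = "") -> None:
    """ranked_hits.csv writer (schema-stable column order)."""
    lead = ["compound_id"] + (["smiles"] if "smiles" in hits.columns else [])
    p_cols = [c for c in hits.columns if c.startswith("p_")]
    extras = [c for c in ("cluster_id", "moa_cluster_id") if c in hits.columns]
    cols = lead + p_cols + ["TA", "TA_weighted", "main_score", "priority"] \
        + extras + ["entropy", "selectivity_flag"]
    out = hits[cols]
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        out.to_csv(fh, index=False)
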