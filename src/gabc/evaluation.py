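"""Benchmarking of interaction scores and condition-level summaries.

Tools to compare enhancer-gene scores against experimentally validated
pairs (precision-recall, ROC, paired AUC difference, rank correlation with
perturbation effect sizes), to measure eQTL support among top-ranked
interactions, to select cell-type-specific genes from an expression
matrix, and to tally interaction sharing across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .io import CandidateEnhancer, GeneModel
from .scoring import anchor_tss

__all__ = [
    "EQTLPair",
    "pr_curve_auprc",
    "roc_auc",
    "compare_roc_paired",
    "score_effect_correlation",
    "eqtl_recall_at_k",
    "select_cs_genes",
    "interaction_overlap_summary",
]


@dataclass(frozen=True)
class EQTLPair:
    """A fine-mapped variant-gene association (position in bp, 0-based)."""

    chrom: str
    position: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("eQTL position must be non-negative")


def _labels_scores(preds: pd.DataFrame):
    y = np.asarray(preds["label"], dtype=int)
    s = np.asarray(preds["score"], dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return y, s


def pr_curve_auprc(preds: pd.DataFrame):
    """Precision-recall curve and its area (step interpolation).

    ``preds`` needs ``score`` and binary ``label`` columns. The curve has
    one point per distinct score threshold (descending, ties grouped);
    the area is the step-wise sum of precision times recall increments.
    """
    y, s = _labels_scores(preds)
    if y.sum() == 0:
        raise ValueError("no positive labels")
    precision, recall, thresholds = precision_recall_curve(y, s)
    # sklearn returns recall decreasing to 0 with a final (1, 0) anchor.
    auprc = float(-np.sum(np.diff(recall) * precision[:-1]))
    curve = pd.DataFrame(
        {
            "threshold": np.append(thresholds, np.nan),
            "precision": precision,
            "recall": recall,
        }
    )
    return curve, auprc


def roc_auc(preds: pd.DataFrame) -> float:
    """ROC AUC: probability a positive outranks a negative (ties = 1/2)."""
    y, s = _labels_scores(preds)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required for ROC AUC")
    return float(roc_auc_score(y, s))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def compare_roc_paired(preds_a: pd.DataFrame, preds_b: pd.DataFrame):
    """Paired test for a difference in ROC AUC between two score sets.

    Both frames must score the identical (region, gene, label) universe.
    Uses the covariance-of-placements construction (DeLong) with a
    two-sided normal reference. Returns ``(delta_auc, p_value)`` with
    delta = AUC(a) - AUC(b).
    """
    key_cols = ["region_id", "gene_id"]
    a = preds_a.sort_values(key_cols).reset_index(drop=True)
    b = preds_b.sort_values(key_cols).reset_index(drop=True)
    if len(a) != len(b) or not (
        a[key_cols + ["label"]].equals(b[key_cols + ["label"]])
    ):
        raise ValueError("prediction universes differ between the two sets")
    y, sa = _labels_scores(a)
    _, sb = _labels_scores(b)
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for idx, s in enumerate((sa, sb)):
        v10[idx], v01[idx] = _placements(s[pos], s[neg])
        aucs[idx] = v10[idx].mean()
    delta = float(aucs[0] - aucs[1])
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return delta, p


def delong_variance(preds_a: pd.DataFrame, preds_b: pd.DataFrame) -> float:
    """Variance of the paired AUC difference (same construction as
    :func:`compare_roc_paired`); exposed for calibration checks."""
    a = preds_a.sort_values(["region_id", "gene_id"]).reset_index(drop=True)
    b = preds_b.sort_values(["region_id", "gene_id"]).reset_index(drop=True)
    y, sa = _labels_scores(a)
    _, sb = _labels_scores(b)
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for idx, s in enumerate((sa, sb)):
        v10[idx], v01[idx] = _placements(s[pos], s[neg])
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    return float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )


def score_effect_correlation(preds: pd.DataFrame) -> float:
    """Spearman rank correlation between score and absolute effect size.

    Ties are mid-ranked. Constant scores make the coefficient undefined;
    NaN is returned with a warning.
    """
    sub = preds.dropna(subset=["effect_size"])
    if len(sub) < 3:
        raise ValueError("need >= 3 pairs with effect sizes")
    s = np.asarray(sub["score"], float)
    e = np.asarray(sub["effect_size"], float)
    if np.all(s == s[0]) or np.all(e == e[0]):
        warnings.warn("constant input; rank correlation undefined",
                      stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(s, e).statistic
    return float(rho)


def eqtl_recall_at_k(
    interactions: pd.DataFrame,
    eqtls: list[EQTLPair],
    enhancers: list[CandidateEnhancer],
    genes: list[GeneModel],
    window: float,
    k: int,
    use_all_tss: bool = True,
) -> float:
    """Fraction of eQTL-supported enhancer-gene pairs among the k
    highest-scored interactions.

    A pair is eQTL-supported when the enhancer contains the variant
    (position in [start, end)) and the eQTL's gene has a TSS within the
    scoring window of that enhancer. Ties at rank k are all included.
    Returns NaN (with a warning) when no pair is supported.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    gene_by_id = {g.gene_id: g for g in genes}
    half = window / 2.0
    supported: set[tuple[str, str]] = set()
    for e in enhancers:
        r = e.region
        for q in eqtls:
            if q.chrom != r.chrom or not (r.start <= q.position < r.end):
                continue
            g = gene_by_id.get(q.gene_id)
            if g is None or g.chrom != r.chrom:
                continue
            tss = anchor_tss(g, use_all_tss)
            if any(abs(r.midpoint - t) <= half for t in tss):
                supported.add((r.region_id, g.gene_id))
    if not supported:
        warnings.warn("no eQTL-supported pairs in the candidate universe",
                      stacklevel=2)
        return float("nan")
    ranked = interactions.sort_values("score", ascending=False)
    if k < len(ranked):
        threshold = ranked["score"].iloc[k - 1]
        top = ranked[ranked["score"] >= threshold]
    else:
        top = ranked
    top_pairs = set(zip(top["region_id"], top["gene_id"]))
    found = supported & top_pairs
    return len(found) / len(supported)


def select_cs_genes(
    expression: pd.DataFrame,
    tpm_floor: float = 0.5,
    z_threshold: float = 2.0,
    ddof: int = 0,
) -> dict[str, set[str]]:
    """Cell-type-specific genes per condition from a gene x condition TPM
    matrix.

    Gene g is specific to condition c iff TPM(g,c) >= ``tpm_floor`` and
    its expression z-score across conditions (population sd by default)
    is >= ``z_threshold``. Genes with zero variance are never specific.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 conditions for a meaningful z-score")
    x = expression.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, -np.inf)
    cs = (z >= z_threshold) & (x >= tpm_floor)
    return {
        cond: set(expression.index[cs[:, j]])
        for j, cond in enumerate(expression.columns)
    }


def interaction_overlap_summary(
    interaction_sets: dict[str, set[tuple[str, str]]],
):
    """Sharing structure of per-condition interaction sets (upset-style).

    Returns ``(subset_counts, per_condition)``: the first maps each
    non-empty condition subset (frozenset) to the number of (region, gene)
    pairs present in exactly that subset; the second is a DataFrame with,
    per condition, the fraction of its interactions shared with all
    conditions and the fraction unique to it.
    """
    if len(interaction_sets) < 2:
        raise ValueError("need >= 2 conditions")
    conds = sorted(interaction_sets)
    membership: dict[tuple[str, str], frozenset] = {}
    universe = set().union(*interaction_sets.values())
    for pair in universe:
        membership[pair] = frozenset(
            c for c in conds if pair in interaction_sets[c]
        )
    counts: dict[frozenset, int] = {}
    for sub in membership.values():
        counts[sub] = counts.get(sub, 0) + 1
    all_set = frozenset(conds)
    rows = []
    for c in conds:
        own = interaction_sets[c]
        n = len(own)
        shared_all = sum(1 for p in own if membership[p] == all_set)
        unique = sum(1 for p in own if membership[p] == frozenset({c}))
        rows.append(
            {
                "condition": c,
                "n_interactions": n,
                "fraction_shared_all": shared_all / n if n else float("nan"),
                "fraction_unique": unique / n if n else float("nan"),
            }
        )
    return counts, pd.DataFrame(rows).set_index("condition")
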