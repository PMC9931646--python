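"""Activity-By-Contact scoring of enhancer-gene interactions.

The classic ABC score of enhancer r for gene g is the activity-contact
product taken relative to all candidate enhancers R_g in a window around
the gene's TSS::

    ABC(r,g) = A_r * C_{r,g} / sum_{i in R_g} A_i * C_{i,g}

so per-gene scores sum to 1 by construction. Two generalizations are
implemented on top:

* gene-specific (adapted) activity: an enhancer's activity is apportioned
  among its candidate target genes G_r by relative contact,
  ``A_{r,g} = A_r * C_{r,g} / sum_{j in G_r} C_{r,j}``, so a promiscuous
  enhancer is not counted at full strength for every gene in reach;
* all-TSS scoring: instead of anchoring each gene at a single (5'-most)
  TSS, activity-contact products are summed over every annotated TSS of
  the gene, in the numerator and over all candidates in the denominator.

With both enabled the score is the gABC score::

    gABC(r,g) = sum_{t in TSS_g} A_{r,t} * C_{r,t}
                / sum_{i in R_g} sum_{t in TSS_g} A_{i,t} * C_{i,t}

All variants are linear in the activity column, so geometry and contact
work is done once per (enhancer, gene) pair and reused across any number
of activity conditions (cell types, clusters, metacells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap, DistanceContactModel
from .io import CandidateEnhancer, GeneModel

__all__ = [
    "ScoringConfig",
    "ScoredInteraction",
    "DegenerateScoreWarning",
    "anchor_tss",
    "enhancers_in_window",
    "genes_in_window",
    "adapted_activity",
    "score_gene",
    "score_all",
    "call_interactions",
]

#: Column order of the interaction tables produced by this module.
INTERACTION_COLUMNS = [
    "region_id",
    "gene_id",
    "condition",
    "activity",
    "adapted_activity",
    "contact",
    "score",
    "distance",
]


class DegenerateScoreWarning(UserWarning):
    """All activity-contact products for a gene/condition are zero."""


@dataclass
class ScoringConfig:
    """Parameters of an ABC/gABC scoring run.

    window
        Total window span in bp around each TSS; candidates are enhancers
        whose midpoint lies within +- window/2 of a TSS. Default 5 Mb.
    cutoff
        Score threshold for calling interactions (inclusive). Default 0.02.
    use_adapted_activity
        Replace A_r by the gene-specific A_{r,g}.
    use_all_tss
        Sum over all annotated TSSs instead of anchoring at the 5' TSS.
        Both flags on = gABC; both off = classic ABC.
    tss_proximal_bp
        Distance below which a region counts as TSS-proximal (used by the
        affinity summarization). Default 2500 bp.
    decay_d0
        Length scale of the exponential distance decay used in affinity
        summarization. Default 5000 bp.
    """

    window: float = 5_000_000
    cutoff: float = 0.02
    use_adapted_activity: bool = True
    use_all_tss: bool = True
    tss_proximal_bp: float = 2500
    decay_d0: float = 5000.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")
        if self.tss_proximal_bp < 0:
            raise ValueError("tss_proximal_bp must be non-negative")
        if self.decay_d0 <= 0:
            raise ValueError("decay_d0 must be positive")


@dataclass(frozen=True)
class ScoredInteraction:
    """One scored (enhancer, gene, condition) triple."""

    region_id: str
    gene_id: str
    condition: str
    activity: float
    adapted_activity: float
    contact: float
    score: float
    distance: float


def anchor_tss(gene: GeneModel, use_all_tss: bool) -> tuple[int, ...]:
    """The TSS positions a gene is represented by under the active mode."""
    return gene.tss if use_all_tss else (gene.five_prime_tss,)


def _lookup(contacts, chrom: str, pos_a: float, pos_b: float) -> float:
    """Contact frequency between two positions on ``chrom``."""
    if isinstance(contacts, dict):
        cmap = contacts.get(chrom)
        if cmap is None:
            raise KeyError(f"no contact map for chromosome {chrom!r}")
        return cmap.lookup(pos_a, pos_b)
    if isinstance(contacts, (ContactMap, DistanceContactModel)):
        return contacts.lookup(pos_a, pos_b)
    raise TypeError(f"unsupported contact source {type(contacts)!r}")


def enhancers_in_window(
    gene: GeneModel,
    enhancers: list[CandidateEnhancer],
    window: float,
    use_all_tss: bool = True,
) -> list[CandidateEnhancer]:
    """Candidate set R_g: enhancers whose midpoint lies within +- window/2
    of any TSS of the gene (the 5'-most TSS only when ``use_all_tss`` is
    off). Deterministic order by coordinate."""
    half = window / 2.0
    tss = anchor_tss(gene, use_all_tss)
    hits = [
        e
        for e in enhancers
        if e.region.chrom == gene.chrom
        and any(abs(e.region.midpoint - t) <= half for t in tss)
    ]
    hits.sort(key=lambda e: (e.region.start, e.region.end, e.region.region_id))
    return hits


def genes_in_window(
    enhancer: CandidateEnhancer,
    genes: list[GeneModel],
    window: float,
    use_all_tss: bool = True,
) -> list[GeneModel]:
    """Candidate target set G_r: genes with at least one TSS within
    +- window/2 of the enhancer midpoint."""
    half = window / 2.0
    mid = enhancer.region.midpoint
    hits = [
        g
        for g in genes
        if g.chrom == enhancer.region.chrom
        and any(abs(mid - t) <= half for t in anchor_tss(g, use_all_tss))
    ]
    hits.sort(key=lambda g: (g.tss[0], g.gene_id))
    return hits


def adapted_activity(
    a_r: float,
    contact_to_target: float,
    contacts_per_gene: list[float],
) -> float:
    """Gene-specific activity A_{r,g} = A_r * C_{r,g} / sum_j C_{r,j}.

    ``contacts_per_gene`` holds one representative contact per gene in G_r
    (each gene's TSS nearest to the enhancer). With a positive pseudocount
    the denominator is always positive; a zero denominator (pseudocount 0
    and no measured contacts) yields 0 rather than NaN.
    """
    denom = float(sum(contacts_per_gene))
    if denom <= 0:
        return 0.0
    return a_r * contact_to_target / denom


# ---------------------------------------------------------------------------
# Scoring engine


class _Engine:
    """Precomputes windows, per-gene contacts and the per-enhancer
    adapted-activity denominators once, then scores any activity column."""

    def __init__(self, enhancers, genes, contacts, config):
        self.enhancers = enhancers
        self.genes = genes
        self.contacts = contacts
        self.config = config
        self._dr_cache: dict[int, float] = {}
        self._gene_anchor = {
            id(g): anchor_tss(g, config.use_all_tss) for g in genes
        }

    def _d_r(self, enh_idx: int) -> float:
        """sum over G_r of the contact to each gene's nearest TSS."""
        if enh_idx in self._dr_cache:
            return self._dr_cache[enh_idx]
        enh = self.enhancers[enh_idx]
        mid = enh.region.midpoint
        half = self.config.window / 2.0
        total = 0.0
        for g in self.genes:
            if g.chrom != enh.region.chrom:
                continue
            tss = self._gene_anchor[id(g)]
            near = min(tss, key=lambda t: abs(mid - t))
            if abs(mid - near) > half:
                continue  # no TSS in window -> g not in G_r
            total += _lookup(self.contacts, g.chrom, mid, near)
        self._dr_cache[enh_idx] = total
        return total

    def gene_rows(self, gene: GeneModel) -> dict | None:
        """Geometry + contact weights for one gene; None if R_g is empty."""
        cfg = self.config
        half = cfg.window / 2.0
        tss = self._gene_anchor[id(gene)]
        cand: list[int] = []
        for idx, e in enumerate(self.enhancers):
            if e.region.chrom != gene.chrom:
                continue
            if any(abs(e.region.midpoint - t) <= half for t in tss):
                cand.append(idx)
        if not cand:
            return None
        cand.sort(
            key=lambda i: (
                self.enhancers[i].region.start,
                self.enhancers[i].region.end,
                self.enhancers[i].region.region_id,
            )
        )
        weights = np.empty(len(cand))
        contact_rep = np.empty(len(cand))
        arg_factor = np.empty(len(cand))  # A_{r,g} / A_r
        dist = np.empty(len(cand))
        for k, idx in enumerate(cand):
            e = self.enhancers[idx]
            mid = e.region.midpoint
            c_t = np.array(
                [_lookup(self.contacts, gene.chrom, mid, t) for t in tss]
            )
            d_t = np.array([abs(mid - t) for t in tss])
            near = int(np.argmin(d_t))
            dist[k] = d_t[near]
            contact_rep[k] = c_t.sum() if cfg.use_all_tss else c_t[0]
            d_r = self._d_r(idx)
            arg_factor[k] = c_t[near] / d_r if d_r > 0 else 0.0
            if cfg.use_adapted_activity:
                # c * (c / D) keeps the singleton-G_r case exactly A_r
                if d_r > 0:
                    w = float((c_t * (c_t / d_r)).sum())
                else:
                    w = 0.0
            else:
                w = float(c_t.sum())
            weights[k] = w
        return {
            "cand": cand,
            "weights": weights,
            "contact": contact_rep,
            "arg_factor": arg_factor,
            "distance": dist,
        }

    def score_gene_frame(
        self, gene: GeneModel, conditions: list[str]
    ) -> pd.DataFrame:
        geo = self.gene_rows(gene)
        if geo is None:
            return pd.DataFrame(columns=INTERACTION_COLUMNS)
        cand = geo["cand"]
        acts = np.array(
            [
                [self.enhancers[i].activity[c] for c in conditions]
                for i in cand
            ],
            dtype=float,
        )
        numer = acts * geo["weights"][:, None]
        denom = numer.sum(axis=0)
        scores = np.zeros_like(numer)
        for j, cond in enumerate(conditions):
            if denom[j] > 0:
                scores[:, j] = numer[:, j] / denom[j]
            else:
                warnings.warn(
                    f"gene {gene.gene_id!r}, condition {cond!r}: all "
                    "activity-contact products are zero; scores set to 0",
                    DegenerateScoreWarning,
                    stacklevel=3,
                )
        n = len(cand)
        frames = []
        ids = [self.enhancers[i].region.region_id for i in cand]
        for j, cond in enumerate(conditions):
            frames.append(
                pd.DataFrame(
                    {
                        "region_id": ids,
                        "gene_id": gene.gene_id,
                        "condition": cond,
                        "activity": acts[:, j],
                        "adapted_activity": acts[:, j] * geo["arg_factor"],
                        "contact": geo["contact"],
                        "score": scores[:, j],
                        "distance": geo["distance"],
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        return out[INTERACTION_COLUMNS]


def _resolve_conditions(enhancers, conditions):
    if not enhancers:
        return conditions or []
    cond_set = set(enhancers[0].activity)
    for e in enhancers:
        if set(e.activity) != cond_set:
            raise ValueError(
                f"enhancer {e.region.region_id!r} has a different condition "
                "set than the rest"
            )
    if conditions is None:
        return sorted(cond_set)
    missing = set(conditions) - cond_set
    if missing:
        raise KeyError(f"unknown condition(s) {sorted(missing)}")
    return list(conditions)


def score_gene(
    gene: GeneModel,
    enhancers: list[CandidateEnhancer],
    genes: list[GeneModel],
    contacts,
    config: ScoringConfig,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Score all candidate enhancers of one gene.

    ``genes`` must be the full gene universe: the adapted-activity
    denominator of each candidate runs over every gene in the enhancer's
    own window, not only ``gene``. Returns a long-format DataFrame with
    one row per (enhancer, condition); per (gene, condition) the scores
    sum to 1 whenever any activity-contact product is positive.
    """
    conditions = _resolve_conditions(enhancers, conditions)
    engine = _Engine(enhancers, genes, contacts, config)
    return engine.score_gene_frame(gene, conditions)


def score_all(
    enhancers: list[CandidateEnhancer],
    genes: list[GeneModel],
    contacts,
    config: ScoringConfig,
    conditions: list[str] | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Score every gene against its candidate enhancers, batched over all
    activity conditions.

    Window geometry, contact lookups and adapted-activity denominators are
    computed once and shared across conditions, so a multi-condition run
    is bit-identical to (and much faster than) per-condition runs. Output
    ordering is canonical: genes by (chrom, first TSS, gene_id), candidates
    by coordinate, conditions in the requested order.
    """
    conditions = _resolve_conditions(enhancers, conditions)
    engine = _Engine(enhancers, genes, contacts, config)
    ordered = sorted(genes, key=lambda g: (g.chrom, g.tss[0], g.gene_id))
    if n_workers > 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=n_workers, prefer="processes")(
            delayed(_score_gene_worker)(
                gene, enhancers, genes, contacts, config, conditions
            )
            for gene in ordered
        )
    else:
        frames = [engine.score_gene_frame(g, conditions) for g in ordered]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _score_gene_worker(gene, enhancers, genes, contacts, config, conditions):
    engine = _Engine(enhancers, genes, contacts, config)
    return engine.score_gene_frame(gene, conditions)


def call_interactions(scored: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep interactions with score >= cutoff (ties kept).

    The many-to-many structure is preserved: a gene may retain several
    enhancers and an enhancer may appear for several genes.
    """
    return scored[scored["score"] >= cutoff].reset_index(drop=True)
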