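"""Independent brute-force oracles.

Literal, loop-based transliterations of the scoring, affinity and metric
definitions, written separately from the production code paths. These are
deliberately slow and naive: every sum is an explicit Python loop over
every (enhancer, TSS) or (threshold, pair) combination.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# ABC / gABC scoring


def _anchors(gene, all_tss):
    if all_tss:
        return list(gene.tss)
    return [gene.tss[0] if gene.strand == "+" else gene.tss[-1]]


def _nearest(tss_list, mid):
    best = tss_list[0]
    for t in tss_list[1:]:
        if abs(mid - t) < abs(mid - best):
            best = t
    return best


def oracle_scores(enhancers, genes, contacts, window, adapted, all_tss,
                  condition):
    """score[(region_id, gene_id)] by direct evaluation of the score
    definitions, summing literally over every (candidate, TSS) pair."""
    half = window / 2.0

    def C(chrom, a, b):
        return contacts.lookup(a, b)

    def in_window(mid, gene):
        return any(abs(mid - t) <= half for t in _anchors(gene, all_tss))

    def G_r(enh):
        return [
            g for g in genes
            if g.chrom == enh.region.chrom and in_window(enh.region.midpoint, g)
        ]

    def denom_r(enh):
        # sum of one representative contact per candidate target gene
        total = 0.0
        for g in G_r(enh):
            t = _nearest(_anchors(g, all_tss), enh.region.midpoint)
            total += C(g.chrom, enh.region.midpoint, t)
        return total

    def a_rt(enh, t):
        a_r = enh.activity[condition]
        if not adapted:
            return a_r
        d = denom_r(enh)
        if d <= 0:
            return 0.0
        return a_r * C(enh.region.chrom, enh.region.midpoint, t) / d

    scores = {}
    for g in genes:
        cands = [
            e for e in enhancers
            if e.region.chrom == g.chrom and in_window(e.region.midpoint, g)
        ]
        numers = {}
        for e in cands:
            total = 0.0
            for t in _anchors(g, all_tss):
                total += a_rt(e, t) * C(g.chrom, e.region.midpoint, t)
            numers[e.region.region_id] = total
        denom = sum(numers.values())
        for rid, num in numers.items():
            scores[(rid, g.gene_id)] = num / denom if denom > 0 else 0.0
    return scores


# ---------------------------------------------------------------------------
# TRAP affinity


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def oracle_energy_matrix(counts, background, lam=0.7, pseudocount=1.0):
    """Hand evaluation of the PFM -> energy conversion formula."""
    energies = []
    for row in counts:
        reg = [c + pseudocount for c in row]
        bmax = reg.index(max(reg))
        cmax = reg[bmax]
        pos = []
        for b in range(4):
            e = (1.0 / lam) * math.log(
                (cmax / reg[b]) * (background[b] / background[bmax])
            )
            pos.append(max(e, 0.0))
        pos[bmax] = 0.0
        energies.append(pos)
    return energies


def oracle_trap_affinity(energies, r0, sequence, lam=0.7):
    """Direct per-site occupancy sum over both strands."""
    w = len(energies)
    seq = sequence.upper()
    if len(seq) < w:
        return 0.0
    rc = "".join(_COMP.get(b, "N") for b in reversed(seq))
    total = 0.0
    for strand_seq in (seq, rc):
        for i in range(len(strand_seq) - w + 1):
            e = 0.0
            for p in range(w):
                b = strand_seq[i + p]
                if b in _IDX:
                    e += energies[p][_IDX[b]]
                else:
                    e += max(energies[p])
            x = r0 * math.exp(-e)
            total += x / (1.0 + x)
    return total


def oracle_summarize(regions, affinity_of, ml, mode, d0, proximal, c_max):
    """Direct summation of the gene-level affinity for one TF.

    ``regions`` is a list of dicts with keys activity, adapted_activity,
    contact, distance, region_id.
    """
    total = 0.0
    for r in regions:
        decay = r["activity"] * math.exp(-r["distance"] / d0)
        if mode == "window":
            m = decay
        elif mode == "gabc":
            m = decay if r["distance"] <= proximal else r["adapted_activity"]
        elif mode == "abc":
            m = (
                decay
                if r["distance"] <= proximal
                else r["activity"] * r["contact"] / c_max
            )
        else:
            raise ValueError(mode)
        total += affinity_of[r["region_id"]] / ml * m
    return total


# ---------------------------------------------------------------------------
# Metrics


def oracle_pr_points(labels, scores):
    """Precision/recall at every distinct threshold, descending."""
    n_pos = sum(labels)
    points = []
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for y, s in zip(labels, scores) if s >= thr and y == 1)
        fp = sum(1 for y, s in zip(labels, scores) if s >= thr and y == 0)
        points.append((thr, tp / (tp + fp), tp / n_pos))
    return points


def oracle_auprc(labels, scores):
    pts = oracle_pr_points(labels, scores)
    area = 0.0
    prev_recall = 0.0
    for _, precision, recall in pts:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def oracle_roc_auc(labels, scores):
    """Pair counting: P(score_pos > score_neg) with ties as 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_jackknife_delta_auc_var(labels, scores_a, scores_b):
    """Delete-one jackknife variance of AUC(a) - AUC(b)."""
    n = len(labels)

    def delta(idx):
        y = [labels[i] for i in idx]
        sa = [scores_a[i] for i in idx]
        sb = [scores_b[i] for i in idx]
        return oracle_roc_auc(y, sa) - oracle_roc_auc(y, sb)

    thetas = []
    for leave in range(n):
        idx = [i for i in range(n) if i != leave]
        y = [labels[i] for i in idx]
        if sum(y) == 0 or sum(y) == len(y):
            continue
        thetas.append(delta(idx))
    mean = sum(thetas) / len(thetas)
    return (len(thetas) - 1) / len(thetas) * sum(
        (t - mean) ** 2 for t in thetas
    )


def oracle_recall_at_k(supported_pairs, ranked_pairs_with_scores, k):
    """Exhaustive set intersection with ties at rank k included."""
    if not supported_pairs:
        return float("nan")
    ranked = sorted(ranked_pairs_with_scores, key=lambda x: -x[2])
    if k < len(ranked):
        thr = ranked[k - 1][2]
        top = {(r, g) for r, g, s in ranked if s >= thr}
    else:
        top = {(r, g) for r, g, _ in ranked}
    return len(supported_pairs & top) / len(supported_pairs)


def oracle_overlap_counts(sets):
    """Membership-vector tally over every pair in the union."""
    conds = sorted(sets)
    counts = {}
    universe = set()
    for s in sets.values():
        universe |= s
    for pair in universe:
        key = frozenset(c for c in conds if pair in sets[c])
        counts[key] = counts.get(key, 0) + 1
    return counts
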