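# gabc

Generalized Activity-By-Contact (gABC) scoring of enhancer–gene
interactions, with gene-level transcription-factor affinity
summarization, multi-cell-type batching, and an evaluation toolkit.

## The problem

Enhancers regulate genes over large genomic distances, and linear
proximity is a poor guide to their targets. The Activity-By-Contact
idea scores each candidate enhancer *r* for each gene *g* by how active
the enhancer is (A_r, read counts from DNase-, ATAC- or H3K27ac
ChIP-seq) and how often it touches the gene's promoter in 3D
(C_{r,g}, from a normalized Hi-C/HiChIP matrix or an inverse-distance
estimate):

```
ABC(r,g) = A_r · C_{r,g} / Σ_{i ∈ R_g} A_i · C_{i,g}
```

where R_g is the set of candidates within a window (default 5 Mb)
around the gene's TSS. Scores per gene sum to 1; interactions are
called above a cutoff (default 0.02).

This package also implements two generalizations, which together form
the **gABC score**:

1. **Gene-specific activity.** An enhancer in contact with many genes
   should not be counted at full strength for each of them. Its
   activity is apportioned among its candidate target genes G_r by
   relative contact: `A_{r,g} = A_r · C_{r,g} / Σ_{j ∈ G_r} C_{r,j}`.
2. **All TSSs.** Genes have several annotated transcription start
   sites; instead of picking the 5′ one, activity–contact products are
   summed over every TSS:

```
gABC(r,g) = Σ_{t ∈ TSS_g} A_{r,t} · C_{r,t}
            / Σ_{i ∈ R_g} Σ_{t ∈ TSS_g} A_{i,t} · C_{i,t}
```

On top of the interaction calls, per-region TF binding affinities are
computed with the biophysical TRAP occupancy model (PFM → mismatch
energy matrix → expected bound molecules, no binding-site threshold)
and summed per gene as `af_{g,tf} = Σ_r (af_{r,tf} / ml_tf) · m_r`,
where the multiplier m_r is the distance-decayed activity
`A_r · e^{−d/d₀}` for TSS-proximal regions (≤ 2.5 kb, d₀ = 5 kb) and
otherwise the adapted activity A_{r,g} (gABC regime) or the
contact-scaled activity `A_r · C_{r,g}/C_max` (ABC regime).

All score variants are linear in the activity column, so one run scores
any number of cell types / clusters / metacells while doing the window
and contact work once.

## Worked example

`python examples/score_toy_locus.py` builds a seeded synthetic locus
(3 genes × 2 TSSs, 6 enhancers, decaying contacts plus one planted
loop) and prints:

```
Planted loop: enhancer E3 <-> gene G1

ABC (condition ct1):
  G1: top enhancer E3 score=0.413 distance=34712 bp (scores sum to 1.000000)
  G2: top enhancer E3 score=0.413 distance=1419 bp (scores sum to 1.000000)
  G3: top enhancer E5 score=0.437 distance=6369 bp (scores sum to 1.000000)

gABC (condition ct1):
  G1: top enhancer E1 score=0.413 distance=4271 bp (scores sum to 1.000000)
  G2: top enhancer E3 score=0.480 distance=472 bp (scores sum to 1.000000)
  G3: top enhancer E5 score=0.654 distance=3673 bp (scores sum to 1.000000)
```

Each score is the fraction of a gene's total activity–contact signal
carried by one enhancer (per-gene sums are exactly 1). Note how gABC
demotes E3 for gene G1: E3 sits close to G2 and contacts several genes,
so its activity is shared out rather than counted in full everywhere.

Other examples: `tf_affinity_matrix.py` (gene × TF matrices with the
three feature columns), `benchmark_metrics.py` (AUPRC / ROC-AUC /
paired AUC test / recall@k), `multi_celltype_run.py` (end-to-end
pipeline over four cell types, interaction sharing, condition-specific
genes).

## Library layout

| module | contents |
| --- | --- |
| `gabc.io` | BED / GTF / activity-table / JASPAR-PFM readers, exclusion filtering, geometric-mean assay combination |
| `gabc.contacts` | sparse binned `ContactMap` with pseudocount, triplet reader, map averaging, inverse-distance fallback |
| `gabc.scoring` | `ScoringConfig`, `score_gene` / `score_all` (ABC, adapted, all-TSS, gABC), `call_interactions` |
| `gabc.affinity` | TRAP energy conversion, region affinities, gene-level summarization (window / abc / gabc), gene features |
| `gabc.evaluation` | PR/ROC curves, paired DeLong AUC comparison, rank correlation, eQTL recall@k, CS-gene selection, sharing tables |
| `gabc.synth` | seeded toy loci, labeled benchmarks, motif fixtures |
| `gabc.pipeline` | `RunConfig` + `run_pipeline` end-to-end orchestration with manifest |

## Acceptance script

`scripts/acceptance.py` regenerates the prescribed toy locus from the
given seed, scores every gene in both ABC and gABC mode, sums the
scores over each gene's candidate set and reports the total farthest
from the analytic value:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
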