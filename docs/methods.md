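# Methods

## Interaction model

The score of candidate enhancer *r* for gene *g* is an activity–contact
product normalized over the gene's candidate set R_g (all enhancers
whose midpoint lies within ± window/2 of a TSS of *g*). Four variants
are controlled by two flags of `ScoringConfig`:

| `use_adapted_activity` | `use_all_tss` | score |
| --- | --- | --- |
| off | off | classic ABC, gene anchored at its 5′-most TSS |
| on | off | adapted activity, single TSS |
| off | on | plain activity summed over all TSSs |
| on | on | gABC |

The adapted activity is `A_{r,g} = A_r · C_{r,g} / Σ_{j∈G_r} C_{r,j}`,
with G_r the genes having a TSS within ± window/2 of the enhancer
midpoint. The off/on combination (all TSSs with unadapted activity) is
not spelled out by the model's defining equations; it is implemented as
the natural analogue (numerator `Σ_t A_r·C_{r,t}`) because the two
generalizations are independently switchable and were evaluated
separately.

Assumptions inherited from the model family: regulation is additive
across enhancers; all genes are regulated the same way; contacts are a
static scaffold (one bulk contact matrix can serve many cell types,
with specificity coming from the activity columns); promoter-overlapping
regions are scored like any other candidate.

### Multi-TSS handling

The adapted-activity denominator needs one contact per gene in G_r; for
multi-TSS genes the TSS nearest to the enhancer is used as the
representative (the defining sum is written per gene, not per TSS).
In all-TSS mode the numerator then sums `A_{r,t}·C_{r,t}` over every
TSS *t* with that same per-gene-collapsed denominator. TSSs of one gene
falling into the same contact bin are *not* merged — the sum runs over
annotated TSSs, so a TSS-dense gene legitimately accumulates repeated
bin contacts.

### Geometry and numerics

* Coordinates: BED intervals are 0-based half-open; GTF is 1-based
  inclusive and converted on read (TSS = transcript start on +, end on
  −). Exact-duplicate TSSs are collapsed.
* Region → bin: floor(midpoint / resolution); TSS → bin:
  floor(tss / resolution). Single-bin attribution keeps denominators
  well defined. Default resolution 5000 bp.
* Window is the total span: a 5 Mb window reaches ± 2.5 Mb from each
  TSS. Default 5 Mb; interaction cutoff 0.02, inclusive (ties kept).
* Pseudocount: added to every contact lookup so all window candidates
  contribute. Default 1e-6 — the inverse-distance estimate at a 1 Mb
  reference distance — configurable; the matrix source's own convention
  takes precedence when known.
* Distance fallback: C(d) = 1 / max(d, min_distance) with
  min_distance = resolution, the fractal-globule-style inverse-distance
  decay.
* Degenerate gene/condition (all activity–contact products zero):
  scores are 0, not NaN, with a `DegenerateScoreWarning`.
* The adapted weight is computed as `c · (c / D_r)` rather than
  `c² / D_r`; mathematically identical, but it makes the single-gene
  window case collapse to the classic score *bit-for-bit* (the ratio is
  exactly 1.0), which the degeneracy tests assert.
* Reported per pair: A_r, A_{r,g}, C_{r,g} (summed over TSSs in
  all-TSS mode), score, and midpoint-to-nearest-TSS distance.

### Batching

Every variant is linear in the activity value, so window membership,
contact lookups and adapted-activity denominators are computed once per
(enhancer, gene) pair and multiplied into each activity column. A
multi-condition run is therefore bit-identical to per-condition runs.
Gene-level parallelism (joblib) merges in canonical order, so the
worker count cannot change results.

## TF affinities

Region affinities follow the TRAP occupancy model. A PFM is regularized
(+1 per cell), and each position's base *b* receives mismatch energy
`E = (1/λ) · ln((c_max/c_b) · (bg_b/bg_max))`, clamped at ≥ 0 with the
consensus base at 0. Background is the average base composition of the
candidate regions themselves (zero frequencies floored at 1e-4).
Parameters λ = 0.7 and `ln R0 = 0.584·W − 5.66` are the published
defaults of the TRAP method; all are configurable. The region affinity
sums `R0·e^{−E} / (1 + R0·e^{−E})` over every site on both strands
(reverse-strand energies are the reverse-complement transform of the
forward matrix); non-ACGT bases take the worst energy at their position
instead of invalidating the site. Low affinities are kept — no
binding-site threshold exists anywhere.

Gene-level summarization multiplies each assigned region's
length-normalized affinity `af_{r,tf}/ml_tf` by a regime-dependent
activity multiplier (see README). In the abc/gabc regimes the assigned
regions are the called interactions *plus* all TSS-proximal regions
(≤ 2500 bp) regardless of score, deduplicated; proximal regions always
use the exponential-decay multiplier because their measured contact is
dominated by self-contact. C_max is the maximum contact over all
region–gene pairs of the whole run (after pseudocount), computed
genome-wide rather than per chromosome — a deliberate choice so the
multiplier scale is comparable across chromosomes. Each gene record
also carries n_regions, mean TSS distance and mean region length
(reported as missing when no region is assigned).

## Evaluation

* AUPRC uses step interpolation over distinct thresholds (ties
  grouped), ROC-AUC the rank statistic with ties counted ½ — both
  delegated to scikit-learn, and cross-checked in the tests against
  exhaustive enumeration oracles.
* The paired AUC comparison uses the covariance-of-placements (DeLong)
  construction with a two-sided normal reference; its variance is
  validated against a delete-one jackknife in the tests. Degenerate
  zero-variance input returns p = 1 when the delta is 0.
* eQTL recall@k: a pair is supported when the enhancer body contains
  the variant and the eQTL's gene has a TSS within the scoring window
  of that enhancer; matching against the top-k requires exact region
  identity (candidate sets coincide by construction), ties at rank k
  included.
* Cell-type-specific genes: TPM ≥ 0.5 and expression z-score ≥ 2
  across conditions, with the *population* standard deviation
  (configurable via `ddof`); zero-variance genes are never specific.
  Note the population z-score is bounded by √(n_conditions − 1), so the
  rule needs at least six conditions to be attainable at z ≥ 2.

## Synthetic data

`make_toy_locus` emulates the structure of real inputs: genes with
several TSSs, enhancer intervals with gamma-distributed activities
(shape 2, scale 20 — a heavy-ish right tail like read-count data),
contacts `round(K/max(d, resolution))` with K = 1e6 (so a 5 kb
neighbour gets ~200, a 1 Mb pair ~1, and the default pseudocount stays
below every planted contact), one planted loop of strength 500, and a
random genome sequence with a fixed consensus planted into every other
enhancer. Everything is deterministic per seed and writes byte-identical
files.

It does **not** model Hi-C matrix noise or normalization artefacts,
single-cell sparsity, GC or mappability bias, or realistic motif
redundancy. A green test on this generator establishes that the
implementation computes its definitions correctly and that planted
signal is recovered — not that the model is biologically accurate on
real data.

`make_labeled_benchmark` samples positive pairs with probability
increasing in the locus' own gABC score (softmax with the
signal-strength temperature); at signal 0 the labels are independent of
the scores, which the null-calibration tests exploit (mean AUC ≈ 0.5
over seeds).

## Known limitations

* Inter-chromosomal contacts are ignored; windows never cross
  chromosomes.
* The activity table must cover every candidate region; there is no
  imputation.
* Contact inputs are taken as already normalized — no balancing is
  applied.
* The gene × TF matrix assumes additive TF influence; it is a hand-off
  for downstream expression models, not a regulatory network.
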