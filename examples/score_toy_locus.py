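"""Score enhancer-gene interactions on a synthetic locus, ABC vs gABC.

Builds a seeded toy locus (3 genes with 2 TSSs each, 6 candidate
enhancers, a decaying contact map with one planted loop), scores it with
the classic ABC model and with the generalized gABC model, and prints the
top-ranked enhancer per gene under each score.
"""

from gabc.scoring import ScoringConfig, score_all
from gabc.synth import make_toy_locus

locus = make_toy_locus(seed=1)
print(f"Planted loop: enhancer {locus.planted_loop[0]} <-> "
      f"gene {locus.planted_loop[1]}\n")

for name, adapted, all_tss in [("ABC", False, False), ("gABC", True, True)]:
    cfg = ScoringConfig(use_adapted_activity=adapted, use_all_tss=all_tss)
    scored = score_all(locus.enhancers, locus.genes, locus.contact_map, cfg)
    ct1 = scored[scored.condition == "ct1"]
    print(f"{name} (condition ct1):")
    for gene_id, block in ct1.groupby("gene_id"):
        top = block.loc[block.score.idxmax()]
        print(f"  {gene_id}: top enhancer {top.region_id} "
              f"score={top.score:.3f} distance={top.distance:.0f} bp "
              f"(scores sum to {block.score.sum():.6f})")
    print()

print("Each score is the fraction of a gene's total activity-contact "
      "signal carried by one enhancer, so per-gene scores sum to 1. The "
      "planted loop boosts its enhancer's contact weight; the final "
      "ranking also reflects each enhancer's measured activity, and gABC "
      "additionally discounts enhancers contacting many genes.")
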