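"""Run the full pipeline on a multi-cell-type locus and compare conditions.

Writes a synthetic locus with four activity columns (cell types) to disk,
runs the end-to-end pipeline (read -> filter -> batched scoring -> call ->
TF affinity matrices -> manifest), then summarizes how interactions are
shared across cell types and which genes are condition-specific.
"""

import json
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from gabc.evaluation import interaction_overlap_summary, select_cs_genes
from gabc.pipeline import RunConfig, run_pipeline
from gabc.synth import make_toy_locus

tmp = Path(tempfile.mkdtemp(prefix="gabc_example_"))
locus = make_toy_locus(seed=4, n_conditions=4, outdir=tmp / "locus")

out = run_pipeline(RunConfig(
    regions=str(tmp / "locus" / "regions.bed"),
    annotation=str(tmp / "locus" / "genes.gtf"),
    activity=str(tmp / "locus" / "activity.tsv"),
    contacts=str(tmp / "locus" / "contacts.tsv"),
    motifs=str(tmp / "locus" / "motifs.jaspar"),
    genome=str(tmp / "locus" / "genome.fa"),
    outdir=str(tmp / "run"),
    cutoff=0.02,
))
manifest = json.loads((out / "manifest.json").read_text())
print("Interactions called per cell type (gABC, cutoff 0.02):")
print(" ", manifest["n_called"])

sets = {}
for cond in locus.conditions:
    tab = pd.read_csv(out / f"interactions_{cond}.tsv", sep="\t")
    called = tab[tab.score_gabc >= 0.02]
    sets[cond] = set(zip(called.region_id, called.gene_id))
counts, per_cond = interaction_overlap_summary(sets)
print("\nSharing of called interactions across cell types:")
print(per_cond.round(3))

# condition specificity of a synthetic expression matrix; note the
# z >= 2 rule needs enough conditions (population z is bounded by
# sqrt(n_conditions - 1)), so we use 8 cell types here
rng = np.random.default_rng(4)
conds8 = [f"ct{i + 1}" for i in range(8)]
expr = pd.DataFrame(
    rng.gamma(2.0, 2.0, size=(len(locus.genes), 8)),
    index=[g.gene_id for g in locus.genes], columns=conds8,
)
expr.iloc[0, 0] *= 20  # make one gene strongly specific to ct1
cs = select_cs_genes(expr)
print("\nCondition-specific genes (TPM >= 0.5, z >= 2):",
      {c: sorted(s) for c, s in cs.items()})
print("\nShared fractions near 1 mean contact structure dominates; "
      "differences come only from the per-cell-type activity columns.")
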