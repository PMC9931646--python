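"""Seeded synthetic loci for testing and demonstration.

Generates a self-consistent toy locus — gene models with multiple TSSs,
candidate enhancers with per-condition activities, a sparse binned contact
map following an inverse-distance decay with planted loops, and a genome
sequence with planted motif occurrences — and writes it in exactly the
formats the readers in :mod:`gabc.io` / :mod:`gabc.contacts` parse. Every
artifact is fully determined by the seed and parameters (same seed =
byte-identical files).

The generator emulates the *structure* of real inputs (coordinate systems,
decaying contacts, loop enrichment, motif-containing open regions), not
their statistical noise: no Hi-C matrix artefacts, no single-cell sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import DEFAULT_PSEUDOCOUNT, ContactMap
from .io import BASES, CandidateEnhancer, GeneModel, GenomicRegion, MotifPFM
from .scoring import ScoringConfig, score_all

__all__ = ["ToyLocus", "make_toy_locus", "make_labeled_benchmark",
           "make_motif_fixture"]

#: Decay constant of the planted contact model: C(d) = round(K / max(d, res)).
CONTACT_DECAY_K = 1_000_000

#: Contact frequency added on top of the decay for the planted loop.
LOOP_STRENGTH = 500.0

#: Consensus sequence planted into half of the enhancers.
PLANTED_CONSENSUS = "TGACGTCA"


@dataclass
class ToyLocus:
    """One synthetic locus with all inputs a scoring run needs."""

    seed: int
    chrom: str
    chrom_length: int
    resolution: int
    conditions: list[str]
    genes: list[GeneModel]
    enhancers: list[CandidateEnhancer]
    contact_map: ContactMap
    sequence: str
    motifs: list[MotifPFM]
    planted_loop: tuple[str, str]
    planted_motif_regions: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def make_toy_locus(
    seed: int,
    n_genes: int = 3,
    n_tss_per_gene: int = 2,
    n_enhancers: int = 6,
    n_conditions: int = 2,
    resolution: int = 5000,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    chrom_length: int | None = None,
    outdir=None,
) -> ToyLocus:
    """Generate a toy locus; optionally write all input files to outdir.

    Contacts are ``round(K / max(d, resolution))`` between every enhancer
    midpoint and TSS bin, plus one planted loop of strength
    ``LOOP_STRENGTH`` between a random enhancer and a random gene. The
    planted loop dominates the decay, so the loop enhancer attains the
    top gABC score for its gene. Activities are gamma-distributed and
    strictly positive; half of the enhancers carry a planted motif
    consensus in the genome sequence.
    """
    if min(n_genes, n_tss_per_gene, n_enhancers, n_conditions) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    gene_pitch = 40_000
    needed = 60_000 + n_genes * gene_pitch + 60_000
    length = chrom_length if chrom_length is not None else needed
    if length < needed:
        raise ValueError(
            f"chromosome too short: need >= {needed} bp for {n_genes} genes"
        )

    genes: list[GeneModel] = []
    for i in range(n_genes):
        anchor = 60_000 + i * gene_pitch
        offsets = np.cumsum(rng.integers(1200, 6000, size=n_tss_per_gene))
        tss = tuple(int(anchor + off) for off in offsets)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i + 1}", chrom, strand, tss))

    conditions = [f"ct{j + 1}" for j in range(n_conditions)]
    lo, hi = 20_000, length - 20_000
    mids = np.sort(rng.integers(lo, hi, size=n_enhancers))
    enhancers: list[CandidateEnhancer] = []
    for i, mid in enumerate(mids):
        half_len = int(rng.integers(150, 750))
        start, end = int(mid - half_len), int(mid + half_len)
        acts = np.round(rng.gamma(shape=2.0, scale=20.0, size=n_conditions), 3)
        acts = np.maximum(acts, 0.001)
        region = GenomicRegion(chrom, start, end, f"E{i + 1}")
        enhancers.append(
            CandidateEnhancer(region, dict(zip(conditions, acts)))
        )

    entries: dict[tuple[int, int], float] = {}

    def add(bin_a: int, bin_b: int, value: float) -> None:
        key = (bin_a, bin_b) if bin_a <= bin_b else (bin_b, bin_a)
        entries[key] = entries.get(key, 0.0) + value

    for e in enhancers:
        b_e = int(e.region.midpoint // resolution)
        for g in genes:
            for t in g.tss:
                d = abs(e.region.midpoint - t)
                v = round(CONTACT_DECAY_K / max(d, resolution))
                if v > 0:
                    add(b_e, int(t // resolution), float(v))
    loop_enh = enhancers[int(rng.integers(len(enhancers)))]
    loop_gene = genes[int(rng.integers(len(genes)))]
    loop_tss = min(
        loop_gene.tss, key=lambda t: abs(loop_enh.region.midpoint - t)
    )
    add(
        int(loop_enh.region.midpoint // resolution),
        int(loop_tss // resolution),
        LOOP_STRENGTH,
    )
    cmap = ContactMap(chrom, resolution, entries, pseudocount)

    seq = rng.choice(list(BASES), size=length)
    planted_ids: list[str] = []
    for e in enhancers[::2]:
        pos = int(e.region.midpoint) - len(PLANTED_CONSENSUS) // 2
        seq[pos : pos + len(PLANTED_CONSENSUS)] = list(PLANTED_CONSENSUS)
        planted_ids.append(e.region.region_id)
    sequence = "".join(seq)

    motifs = [
        _peaked_pfm("PLANTED", PLANTED_CONSENSUS),
        MotifPFM("CONTROL", np.full((len(PLANTED_CONSENSUS), 4), 25.0)),
    ]

    locus = ToyLocus(
        seed=seed,
        chrom=chrom,
        chrom_length=length,
        resolution=resolution,
        conditions=conditions,
        genes=genes,
        enhancers=enhancers,
        contact_map=cmap,
        sequence=sequence,
        motifs=motifs,
        planted_loop=(loop_enh.region.region_id, loop_gene.gene_id),
        planted_motif_regions=planted_ids,
    )
    if outdir is not None:
        _write_locus(locus, Path(outdir))
    return locus


def _peaked_pfm(name: str, consensus: str, total: int = 100) -> MotifPFM:
    counts = np.ones((len(consensus), 4))
    for p, base in enumerate(consensus):
        counts[p, BASES.index(base)] = total - 3
    return MotifPFM(name, counts)


def _write_locus(locus: ToyLocus, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "regions": outdir / "regions.bed",
        "annotation": outdir / "genes.gtf",
        "activity": outdir / "activity.tsv",
        "contacts": outdir / "contacts.tsv",
        "genome": outdir / "genome.fa",
        "motifs": outdir / "motifs.jaspar",
    }
    with open(paths["regions"], "w") as fh:
        for e in locus.enhancers:
            r = e.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")
    with open(paths["annotation"], "w") as fh:
        for g in locus.genes:
            for k, t in enumerate(g.tss):
                if g.strand == "+":
                    start1, end1 = t + 1, t + 2000
                else:
                    start1, end1 = max(1, t + 1 - 1999), t + 1
                attrs = (
                    f'gene_id "{g.gene_id}"; '
                    f'transcript_id "{g.gene_id}.T{k + 1}";'
                )
                fh.write(
                    f"{g.chrom}\tsynth\ttranscript\t{start1}\t{end1}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
    with open(paths["activity"], "w") as fh:
        fh.write("region_id\t" + "\t".join(locus.conditions) + "\n")
        for e in locus.enhancers:
            vals = "\t".join(
                f"{e.activity[c]:.3f}" for c in locus.conditions
            )
            fh.write(f"{e.region.region_id}\t{vals}\n")
    with open(paths["contacts"], "w") as fh:
        res = locus.resolution
        for (bi, bj), v in sorted(locus.contact_map.entries.items()):
            fh.write(f"{bi * res}\t{bj * res}\t{v:g}\n")
    with open(paths["genome"], "w") as fh:
        fh.write(f">{locus.chrom}\n")
        for i in range(0, len(locus.sequence), 80):
            fh.write(locus.sequence[i : i + 80] + "\n")
    with open(paths["motifs"], "w") as fh:
        for m in locus.motifs:
            fh.write(f">{m.tf_name}\n")
            for b_idx, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in m.counts[:, b_idx])
                fh.write(f"{base} [ {row} ]\n")
    locus.paths = paths


def make_labeled_benchmark(
    seed: int,
    locus: ToyLocus,
    n_positive: int = 6,
    n_negative: int = 9,
    signal_strength: float = 1.0,
    config: ScoringConfig | None = None,
    path=None,
) -> pd.DataFrame:
    """A labeled (region, gene) pair table over a toy locus.

    Positives are sampled with probability increasing in the planted
    regulatory strength (the gABC score on the locus); at
    ``signal_strength=0`` labels are independent of scores, so any ranking
    metric sits at its null value in expectation. Effect sizes for
    positives grow with the score plus noise.
    """
    if signal_strength < 0:
        raise ValueError("signal_strength must be >= 0")
    rng = np.random.default_rng(seed)
    cfg = config or ScoringConfig()
    scored = score_all(
        locus.enhancers, locus.genes, locus.contact_map, cfg,
        conditions=[locus.conditions[0]],
    )
    pairs = scored[["region_id", "gene_id", "score"]].reset_index(drop=True)
    n_total = n_positive + n_negative
    if n_total > len(pairs):
        raise ValueError(
            f"locus has only {len(pairs)} pairs; requested {n_total}"
        )
    s = pairs["score"].to_numpy()
    z = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
    weights = np.exp(signal_strength * z)
    probs = weights / weights.sum()
    pos_idx = rng.choice(len(pairs), size=n_positive, replace=False, p=probs)
    rest = np.setdiff1d(np.arange(len(pairs)), pos_idx)
    neg_idx = rng.choice(rest, size=n_negative, replace=False)
    rows = []
    for idx in np.concatenate([pos_idx, neg_idx]):
        label = 1 if idx in set(pos_idx) else 0
        score = float(pairs["score"].iloc[idx])
        effect = (
            abs(signal_strength * score + rng.normal(0, 0.05))
            if label
            else abs(rng.normal(0, 0.02))
        )
        rows.append(
            {
                "region_id": pairs["region_id"].iloc[idx],
                "gene_id": pairs["gene_id"].iloc[idx],
                "score": score,
                "label": label,
                "effect_size": round(effect, 6),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["region_id", "gene_id"]
    ).reset_index(drop=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


def make_motif_fixture(
    seed: int,
    width: int = 8,
    n_planted_sites: int = 3,
    sequence_length: int = 400,
    outdir=None,
) -> dict:
    """A sharply peaked PFM plus sequences with/without planted sites.

    Returns a dict with the :class:`MotifPFM`, its consensus, the planted
    and background sequences and the planted positions; optionally writes
    a JASPAR file and a two-record FASTA.
    """
    if width > sequence_length:
        raise ValueError("motif wider than sequence")
    rng = np.random.default_rng(seed)
    consensus = "".join(rng.choice(list(BASES), size=width))
    pfm = _peaked_pfm(f"SYN{seed}", consensus)
    planted = rng.choice(list(BASES), size=sequence_length)
    background = "".join(rng.choice(list(BASES), size=sequence_length))
    positions = []
    if n_planted_sites > 0:
        slots = np.linspace(
            0, sequence_length - width, n_planted_sites, dtype=int
        )
        for pos in slots:
            planted[pos : pos + width] = list(consensus)
            positions.append(int(pos))
    planted_seq = "".join(planted)
    out = {
        "pfm": pfm,
        "consensus": consensus,
        "planted_sequence": planted_seq,
        "background_sequence": background,
        "positions": positions,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        motif_path = outdir / "motif.jaspar"
        with open(motif_path, "w") as fh:
            fh.write(f">{pfm.tf_name}\n")
            for b_idx, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in pfm.counts[:, b_idx])
                fh.write(f"{base} [ {row} ]\n")
        fasta_path = outdir / "sequences.fa"
        with open(fasta_path, "w") as fh:
            fh.write(">planted\n" + planted_seq + "\n")
            fh.write(">background\n" + background + "\n")
        out["paths"] = {"motif": motif_path, "fasta": fasta_path}
    return out
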