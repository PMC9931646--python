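"""Biophysical TF binding affinities and their gene-level summarization.

Per-region affinities follow the TRAP model: a position frequency matrix
is converted to a position-specific mismatch-energy matrix (relative to a
background nucleotide composition, here the average composition of the
candidate regions themselves), and the expected number of bound TF
molecules in a region is the summed equilibrium occupancy
R0 * exp(-E) / (1 + R0 * exp(-E)) over every W-mer site on both strands.
Low affinities are retained, never thresholded.

Gene-level summaries combine per-region affinities with the enhancer-gene
assignment. Three regimes are supported (region multiplier m_r):

* ``window``: every candidate region in the window contributes
  ``A_r * exp(-d_rg / d0)`` (exponential decay, d0 = 5 kb);
* ``gabc``: regions assigned by the gABC score contribute their adapted
  activity ``A_rg``, except TSS-proximal regions (<= 2.5 kb) which keep
  the decay form (their measured contact is mostly self-contact);
* ``abc``: as ``gabc`` but distal regions contribute
  ``A_r * C_rg / C_max`` with C_max the maximum contact over all
  region-gene pairs in the run, keeping the multiplier in [0, 1].

The gene-level affinity is ``af_g,tf = sum_r (af_r,tf / ml_tf) * m_r``
with ml_tf the motif length. Three auxiliary gene features are reported:
region count, mean TSS distance and mean region length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io import BASES, GenomicRegion, MotifPFM
from .scoring import ScoringConfig

__all__ = [
    "TRAP_LAMBDA",
    "BackgroundComposition",
    "EnergyMatrix",
    "GeneTFRecord",
    "default_ln_r0",
    "background_composition",
    "pfm_to_energy",
    "trap_region_affinity",
    "region_affinity_matrix",
    "assign_regions",
    "summarize_gene_tf",
    "gene_features",
    "gene_tf_matrix",
    "region_sequences",
]

#: TRAP energy-scale parameter lambda.
TRAP_LAMBDA = 0.7

#: Floor applied to zero background frequencies to keep energies finite.
BACKGROUND_FLOOR = 1e-4

#: Regularization pseudocount added to every PFM cell.
PFM_PSEUDOCOUNT = 1.0

_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT encoding
_CODE = {b: i for i, b in enumerate(BASES)}

FEATURE_COLUMNS = ["n_regions", "mean_tss_distance", "mean_region_length"]


def default_ln_r0(width: int) -> float:
    """ln R0 as a linear function of motif width: 0.584 * W - 5.66."""
    return 0.584 * width - 5.66


@dataclass(frozen=True)
class BackgroundComposition:
    """Genome-background base frequencies (ACGT order, summing to 1)."""

    frequencies: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if (freqs < 0).any():
            raise ValueError("background frequencies must be non-negative")
        if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundComposition":
        return cls((0.25, 0.25, 0.25, 0.25))


@dataclass
class EnergyMatrix:
    """Position-specific mismatch energies for one TF motif.

    ``energies`` is W x 4 (ACGT); the preferred base at each position has
    energy 0 and all energies are non-negative. ``r0`` is the equilibrium
    constant factor of the occupancy model.
    """

    tf_name: str
    energies: np.ndarray
    lam: float = TRAP_LAMBDA
    r0: float = 0.0

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError("energies must be W x 4")
        if (self.energies < -1e-12).any():
            raise ValueError("energies must be non-negative")
        if not np.isclose(self.energies.min(axis=1), 0.0).all():
            raise ValueError("each position needs a zero-energy base")
        if self.r0 <= 0:
            self.r0 = math.exp(default_ln_r0(self.width))

    @property
    def width(self) -> int:
        return self.energies.shape[0]


def background_composition(sequences) -> BackgroundComposition:
    """Average nucleotide composition of a collection of sequences.

    Non-ACGT characters are skipped. Zero frequencies are floored at
    ``BACKGROUND_FLOOR`` (then renormalized) so mismatch energies against
    an absent base stay finite.
    """
    counts = np.zeros(4)
    for seq in sequences:
        up = str(seq).upper()
        for i, b in enumerate(BASES):
            counts[i] += up.count(b)
    if counts.sum() == 0:
        raise ValueError("no usable (ACGT) bases in the input sequences")
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, BACKGROUND_FLOOR)
    freqs = freqs / freqs.sum()
    return BackgroundComposition(tuple(freqs))


def pfm_to_energy(
    pfm: MotifPFM,
    background: BackgroundComposition,
    lam: float = TRAP_LAMBDA,
    pseudocount: float = PFM_PSEUDOCOUNT,
    ln_r0: float | None = None,
) -> EnergyMatrix:
    """Convert a position frequency matrix to a TRAP energy matrix.

    Counts are regularized with ``pseudocount``; per position, the base b
    gets energy ``(1/lam) * ln((c_max / c_b) * (bg_b / bg_max))`` where
    c_max and bg_max refer to the position's maximal-count base, clamped
    at >= 0 so the consensus base sits at energy 0.
    """
    bg = np.asarray(background.frequencies)
    counts = pfm.counts + pseudocount
    if (counts <= 0).any():
        raise ValueError(f"{pfm.tf_name}: non-positive regularized count")
    energies = np.zeros_like(counts)
    for p in range(pfm.width):
        bmax = int(np.argmax(counts[p]))  # first base on ties (ACGT order)
        cmax = counts[p, bmax]
        e = (1.0 / lam) * np.log((cmax / counts[p]) * (bg / bg[bmax]))
        energies[p] = np.maximum(e, 0.0)
        energies[p, bmax] = 0.0
    r0 = math.exp(ln_r0 if ln_r0 is not None else default_ln_r0(pfm.width))
    return EnergyMatrix(pfm.tf_name, energies, lam, r0)


def _encode(sequence: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in sequence.upper()], dtype=np.int64)


def _site_energies(codes: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Summed mismatch energy of every W-mer site (one strand).

    Non-ACGT bases take the worst (maximal) energy at their position.
    """
    w = energies.shape[0]
    ext = np.hstack([energies, energies.max(axis=1, keepdims=True)])
    windows = sliding_window_view(codes, w)
    return ext[np.arange(w)[None, :], windows].sum(axis=1)


def trap_region_affinity(em: EnergyMatrix, sequence: str) -> float:
    """Expected number of bound TF molecules in a region (both strands).

    Sums the occupancy R0 * exp(-E_i) / (1 + R0 * exp(-E_i)) over every
    site i on forward and reverse strand. Sequences shorter than the motif
    have affinity 0.
    """
    codes = _encode(sequence)
    if codes.size < em.width:
        return 0.0
    rc_energies = em.energies[::-1][:, _COMPLEMENT]
    total = 0.0
    for mat in (em.energies, rc_energies):
        e = _site_energies(codes, mat)
        x = em.r0 * np.exp(-e)
        total += float((x / (1.0 + x)).sum())
    return total


def region_sequences(fasta, regions: list[GenomicRegion]) -> dict[str, str]:
    """Extract region sequences from an (indexed) FASTA file."""
    from pyfaidx import Fasta

    fa = fasta if not isinstance(fasta, (str, bytes)) else Fasta(str(fasta))
    return {
        r.region_id: str(fa[r.chrom][r.start : r.end]) for r in regions
    }


def region_affinity_matrix(
    sequences: dict[str, str],
    energy_matrices: list[EnergyMatrix],
) -> pd.DataFrame:
    """Affinity of every TF in every region (rows = regions, cols = TFs)."""
    data = {
        em.tf_name: [
            trap_region_affinity(em, sequences[rid]) for rid in sequences
        ]
        for em in energy_matrices
    }
    return pd.DataFrame(data, index=list(sequences))


@dataclass
class GeneTFRecord:
    """Summarized TF affinities and features for one gene/condition."""

    gene_id: str
    condition: str
    affinities: dict[str, float]
    n_regions: int
    mean_tss_distance: float  # NaN when n_regions == 0
    mean_region_length: float  # NaN when n_regions == 0


def assign_regions(
    scored: pd.DataFrame,
    mode: str,
    config: ScoringConfig,
) -> pd.DataFrame:
    """Select the region-gene pairs feeding the summarization.

    ``window`` keeps every scored candidate pair; ``abc``/``gabc`` keep
    called interactions (score >= cutoff) plus all TSS-proximal pairs
    (distance <= ``config.tss_proximal_bp``) regardless of score,
    deduplicated.
    """
    if mode == "window":
        return scored
    if mode in ("abc", "gabc"):
        keep = (scored["score"] >= config.cutoff) | (
            scored["distance"] <= config.tss_proximal_bp
        )
        return scored[keep]
    raise ValueError(f"unknown summarization mode {mode!r}")


def _multipliers(
    assigned: pd.DataFrame,
    mode: str,
    config: ScoringConfig,
    c_max: float | None,
) -> np.ndarray:
    decay = assigned["activity"].to_numpy() * np.exp(
        -assigned["distance"].to_numpy() / config.decay_d0
    )
    if mode == "window":
        return decay
    proximal = assigned["distance"].to_numpy() <= config.tss_proximal_bp
    if mode == "gabc":
        distal = assigned["adapted_activity"].to_numpy()
    else:  # abc
        if c_max is None or not c_max > 0:
            raise ValueError("abc summarization requires C_max > 0")
        distal = (
            assigned["activity"].to_numpy()
            * assigned["contact"].to_numpy()
            / c_max
        )
    return np.where(proximal, decay, distal)


def summarize_gene_tf(
    gene_id: str,
    condition: str,
    assigned: pd.DataFrame,
    affinities: pd.DataFrame,
    motif_widths: dict[str, int],
    mode: str,
    config: ScoringConfig,
    c_max: float | None = None,
    region_lengths: dict[str, int] | None = None,
) -> GeneTFRecord:
    """Summarize per-region TF affinities into one gene-level record.

    ``assigned`` holds this gene's assigned region rows (columns
    region_id, activity, adapted_activity, contact, distance);
    ``affinities`` is the region x TF affinity matrix; ``c_max`` is the
    run-wide maximum contact, required in ``abc`` mode.
    """
    n = len(assigned)
    if n == 0:
        return GeneTFRecord(
            gene_id,
            condition,
            {tf: 0.0 for tf in affinities.columns},
            0,
            float("nan"),
            float("nan"),
        )
    m_r = _multipliers(assigned, mode, config, c_max)
    af_rows = affinities.loc[assigned["region_id"]]
    widths = np.array([motif_widths[tf] for tf in affinities.columns], float)
    summed = (af_rows.to_numpy() / widths[None, :] * m_r[:, None]).sum(axis=0)
    mean_dist = float(assigned["distance"].mean())
    if region_lengths is not None:
        mean_len = float(
            np.mean([region_lengths[r] for r in assigned["region_id"]])
        )
    elif "length" in assigned.columns:
        mean_len = float(assigned["length"].mean())
    else:
        mean_len = float("nan")
    return GeneTFRecord(
        gene_id,
        condition,
        dict(zip(affinities.columns, summed)),
        n,
        mean_dist,
        mean_len,
    )


def gene_features(assigned: pd.DataFrame, region_lengths: dict[str, int]):
    """(n_regions, mean TSS distance, mean region length) for one gene."""
    n = len(assigned)
    if n == 0:
        return 0, float("nan"), float("nan")
    mean_dist = float(assigned["distance"].mean())
    mean_len = float(np.mean([region_lengths[r] for r in assigned["region_id"]]))
    return n, mean_dist, mean_len


def gene_tf_matrix(
    scored: pd.DataFrame,
    condition: str,
    affinities: pd.DataFrame,
    motif_widths: dict[str, int],
    mode: str,
    config: ScoringConfig,
    region_lengths: dict[str, int],
) -> pd.DataFrame:
    """Gene x (TF + feature) matrix for one condition.

    ``scored`` is the full scored interaction table of the run (all
    conditions); C_max for ``abc`` mode is taken genome-wide over all
    region-gene pairs of the run, after pseudocount.
    """
    sub = scored[scored["condition"] == condition]
    c_max = float(scored["contact"].max()) if len(scored) else 0.0
    records = []
    for gene_id, block in sub.groupby("gene_id", sort=True):
        assigned = assign_regions(block, mode, config)
        rec = summarize_gene_tf(
            gene_id,
            condition,
            assigned,
            affinities,
            motif_widths,
            mode,
            config,
            c_max=c_max,
            region_lengths=region_lengths,
        )
        row = dict(rec.affinities)
        row["n_regions"] = rec.n_regions
        row["mean_tss_distance"] = rec.mean_tss_distance
        row["mean_region_length"] = rec.mean_region_length
        records.append(pd.Series(row, name=gene_id))
    out = pd.DataFrame(records)
    out.index.name = "gene_id"
    return out
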