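"""Reading and validation of genomic input formats.

Parses candidate enhancer regions (BED), gene annotations with all
transcript start sites (GTF), per-region activity tables, JASPAR-style
position frequency matrices and exclusion-region BED files into the
package's internal data model. Coordinates are handled in the standard
dialects: BED is 0-based half-open, GTF is 1-based inclusive and converted
on read, so interval overlap tests are bit-exact.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicRegion",
    "CandidateEnhancer",
    "GeneModel",
    "MotifPFM",
    "GabcParseError",
    "read_regions",
    "write_regions",
    "read_gene_annotation",
    "load_activity",
    "combine_activity_assays",
    "filter_excluded_regions",
    "read_pfms",
]

BASES = "ACGT"


class GabcParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.region_id}: start {self.start} < 0")
        if self.start >= self.end:
            raise ValueError(
                f"{self.region_id}: start {self.start} >= end {self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateEnhancer:
    """A candidate regulatory region with per-condition activity A_r.

    ``activity`` maps condition name (e.g. a cell type or cluster) to a
    non-negative activity value (read count, RPKM, or a geometric-mean
    combination of two assays).
    """

    region: GenomicRegion
    activity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, val in self.activity.items():
            if val < 0:
                raise ValueError(
                    f"{self.region.region_id}: negative activity {val!r} "
                    f"in condition {cond!r}"
                )


@dataclass
class GeneModel:
    """A gene with the complete set of annotated TSS positions.

    ``tss`` holds deduplicated 0-based positions, sorted ascending. The
    5'-most TSS is ``tss[0]`` on the + strand and ``tss[-1]`` on the
    - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: tuple[int, ...]
    expression: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tss:
            raise ValueError(f"{self.gene_id}: no TSS positions")
        dedup = tuple(sorted(set(int(t) for t in self.tss)))
        object.__setattr__(self, "tss", dedup)

    @property
    def five_prime_tss(self) -> int:
        return self.tss[0] if self.strand == "+" else self.tss[-1]


@dataclass
class MotifPFM:
    """A position frequency matrix over ACGT.

    ``counts`` is a W x 4 non-negative array (rows = positions, columns in
    ACGT order); ``width`` is the motif length ml_tf.
    """

    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.tf_name}: counts must be W x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"{self.tf_name}: empty motif")
        if (self.counts < 0).any():
            raise ValueError(f"{self.tf_name}: negative counts")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError(f"{self.tf_name}: all-zero position")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path) -> list[GenomicRegion]:
    """Read genomic regions from a BED file (>=3 columns).

    IDs come from column 4 when present, otherwise ``chrom:start-end``.
    Comment (#), ``track`` and ``browser`` lines are skipped. Malformed
    coordinates raise :class:`GabcParseError` naming the line number.
    """
    regions: list[GenomicRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GabcParseError(
                    f"{path}, line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GabcParseError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from exc
            if start < 0 or start >= end:
                raise GabcParseError(
                    f"{path}, line {lineno}: invalid interval "
                    f"[{start}, {end})"
                )
            rid = fields[3] if len(fields) >= 4 and fields[3] else None
            if rid is None:
                rid = f"{chrom}:{start}-{end}"
            if rid in seen:
                raise GabcParseError(
                    f"{path}, line {lineno}: duplicate region id {rid!r}"
                )
            seen.add(rid)
            regions.append(GenomicRegion(chrom, start, end, rid))
    return regions


def write_regions(regions: list[GenomicRegion], path) -> None:
    """Write regions as 4-column BED (round-trips with read_regions)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# GTF gene annotation

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(path, feature: str = "transcript") -> list[GeneModel]:
    """Read gene models with all annotated TSSs from a GTF file.

    One :class:`GeneModel` per ``gene_id`` over all its ``feature`` records
    (default ``transcript``). The TSS is the transcript start for + strand
    genes and the transcript end for - strand genes, converted from the
    GTF's 1-based inclusive coordinates to 0-based positions. Exact
    duplicate TSS positions are collapsed; distinct ones are all kept.

    Records without a ``gene_id`` attribute are skipped with a single
    summary warning. A gene with records on two chromosomes raises
    :class:`GabcParseError`.
    """
    tss_by_gene: dict[str, set[int]] = {}
    meta: dict[str, tuple[str, str]] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GabcParseError(
                    f"{path}, line {lineno}: expected 9 GTF columns"
                )
            chrom, _, feat, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feat != feature:
                continue
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                n_skipped += 1
                continue
            gene_id = m.group(1)
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GabcParseError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from exc
            if strand not in "+-":
                raise GabcParseError(
                    f"{path}, line {lineno}: strand must be '+' or '-'"
                )
            # 1-based inclusive -> 0-based: start-1 for +, end-1 for -
            tss0 = start1 - 1 if strand == "+" else end1 - 1
            if gene_id in meta:
                prev_chrom, prev_strand = meta[gene_id]
                if prev_chrom != chrom:
                    raise GabcParseError(
                        f"{path}: gene {gene_id!r} spans chromosomes "
                        f"{prev_chrom} and {chrom}"
                    )
            else:
                meta[gene_id] = (chrom, strand)
                tss_by_gene[gene_id] = set()
            tss_by_gene[gene_id].add(tss0)
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} {feature} record(s) without gene_id",
            stacklevel=2,
        )
    return [
        GeneModel(gid, meta[gid][0], meta[gid][1], tuple(sorted(positions)))
        for gid, positions in tss_by_gene.items()
    ]


# ---------------------------------------------------------------------------
# Activity tables


def load_activity(
    path,
    regions: list[GenomicRegion],
    normalize: str = "none",
) -> list[CandidateEnhancer]:
    """Attach per-condition activity columns to candidate regions.

    The table is tab-separated with a header row of condition names and the
    region id in the first column. ``normalize='rpkm'`` converts raw counts
    v for a region of length L (bp) in a column with total T to
    v * 1e9 / (L * T); ``'none'`` passes values through.
    """
    if normalize not in ("none", "rpkm"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    tab = pd.read_csv(path, sep="\t", index_col=0)
    if tab.shape[1] < 1:
        raise GabcParseError(f"{path}: no activity columns")
    missing = [r.region_id for r in regions if r.region_id not in tab.index]
    if missing:
        raise GabcParseError(
            f"{path}: {len(missing)} region(s) missing from activity table: "
            f"{missing[:10]}"
        )
    tab = tab.loc[[r.region_id for r in regions]]
    values = tab.to_numpy(dtype=float)
    if (values < 0).any():
        raise GabcParseError(f"{path}: negative activity values")
    if normalize == "rpkm":
        totals = values.sum(axis=0)
        zero_cols = tab.columns[totals == 0].tolist()
        if zero_cols:
            raise GabcParseError(
                f"{path}: zero library size in column(s) {zero_cols}"
            )
        lengths = np.array([r.length for r in regions], dtype=float)
        values = values * 1e9 / (lengths[:, None] * totals[None, :])
    conditions = list(tab.columns)
    return [
        CandidateEnhancer(region, dict(zip(conditions, row)))
        for region, row in zip(regions, values)
    ]


def combine_activity_assays(a1, a2):
    """Combine two activity columns by the per-region geometric mean.

    Inputs are mappings region_id -> value (or pandas Series) over the same
    region set; the result is sqrt(a1 * a2) per region.
    """
    s1, s2 = pd.Series(dict(a1)), pd.Series(dict(a2))
    if set(s1.index) != set(s2.index):
        raise ValueError("mismatched region sets between the two assays")
    s2 = s2.loc[s1.index]
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("activity values must be non-negative")
    return dict(np.sqrt(s1 * s2))


# ---------------------------------------------------------------------------
# Exclusion regions


def filter_excluded_regions(
    enhancers: list[CandidateEnhancer],
    exclusion: list[GenomicRegion],
) -> tuple[list[CandidateEnhancer], int]:
    """Drop enhancers overlapping any exclusion interval (>=1 bp, half-open).

    Returns the kept enhancers (original order) and the number removed.
    Typical use is masking blacklist regions that accumulate anomalous
    read counts. An empty exclusion set is the identity.
    """
    if not enhancers or not exclusion:
        return list(enhancers), 0
    enh_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [e.region.chrom for e in enhancers],
                "Start": [e.region.start for e in enhancers],
                "End": [e.region.end for e in enhancers],
                "Name": [e.region.region_id for e in enhancers],
            }
        )
    )
    excl_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [x.chrom for x in exclusion],
                "Start": [x.start for x in exclusion],
                "End": [x.end for x in exclusion],
            }
        )
    )
    hit = enh_pr.overlap(excl_pr)
    bad = set(hit.df["Name"]) if len(hit) else set()
    kept = [e for e in enhancers if e.region.region_id not in bad]
    return kept, len(enhancers) - len(kept)


# ---------------------------------------------------------------------------
# JASPAR-style PFMs

_BRACKETS_RE = re.compile(r"[\[\]]")


def read_pfms(path) -> list[MotifPFM]:
    """Read TF motifs from a JASPAR-style PFM text file.

    Each record is a ``>`` header line followed by four base rows in any
    of the common layouts (``A [ 1 2 3 ]`` or ``A 1 2 3`` or bare numeric
    rows in ACGT order). Ragged rows raise an error naming the motif.
    """
    motifs: list[MotifPFM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush() -> None:
        nonlocal name, rows, order
        if name is None:
            return
        if set(rows) != set(BASES):
            raise GabcParseError(
                f"{path}: motif {name!r} missing base rows "
                f"{sorted(set(BASES) - set(rows))}"
            )
        widths = {len(rows[b]) for b in BASES}
        if len(widths) != 1:
            raise GabcParseError(
                f"{path}: motif {name!r} has rows of unequal length"
            )
        counts = np.array([rows[b] for b in BASES], dtype=float).T
        motifs.append(MotifPFM(name, counts))
        name, rows, order = None, {}, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else line[1:]
                continue
            if name is None:
                raise GabcParseError(f"{path}: data before first '>' header")
            clean = _BRACKETS_RE.sub(" ", line)
            parts = clean.split()
            if parts[0].upper() in BASES and not _is_number(parts[0]):
                base = parts[0].upper()
                vals = parts[1:]
            else:
                base = BASES[len(order)] if len(order) < 4 else None
                vals = parts
            if base is None or base in rows:
                raise GabcParseError(
                    f"{path}: motif {name!r} has malformed base rows"
                )
            try:
                rows[base] = [float(v) for v in vals]
            except ValueError as exc:
                raise GabcParseError(
                    f"{path}: motif {name!r} has non-numeric counts"
                ) from exc
            order.append(base)
    flush()
    return motifs


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return not math.isnan(float(token))
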