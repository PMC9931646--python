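"""Chromatin contact frequency sources.

Contact frequency C(r,g) between an enhancer and a TSS comes either from a
binned, already-normalized sparse contact matrix (Hi-C / HiChIP style) with
a pseudocount added to every lookup, or from a distance-decay closed form
(inverse linear distance, the fractal-globule estimate) when no contact
data is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io import GabcParseError

__all__ = [
    "DEFAULT_RESOLUTION",
    "DEFAULT_PSEUDOCOUNT",
    "ContactMap",
    "DistanceContactModel",
    "read_contact_triples",
    "average_contact_maps",
]

#: Default bin size in bp (typical high-resolution Hi-C).
DEFAULT_RESOLUTION = 5000

#: Default pseudocount: the inverse-distance estimate at a reference
#: distance of 1 Mb. Guarantees every candidate in the window contributes.
DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class ContactMap:
    """Sparse symmetric binned contact frequencies for one chromosome.

    Entries are stored upper-triangular ((i, j) with i <= j); lookups are
    symmetric. ``pseudocount`` is added to every lookup so that candidates
    without a measured contact still receive a non-zero frequency.
    """

    chrom: str
    resolution: int
    entries: dict[tuple[int, int], float] = field(default_factory=dict)
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        for (i, j), v in self.entries.items():
            if i > j:
                raise ValueError(f"entry ({i},{j}) not upper-triangular")
            if v < 0:
                raise ValueError(f"negative frequency at ({i},{j})")

    def bin_of(self, pos: float) -> int:
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        return int(pos // self.resolution)

    def set(self, bin_i: int, bin_j: int, value: float) -> None:
        if value < 0:
            raise ValueError("negative contact frequency")
        key = (bin_i, bin_j) if bin_i <= bin_j else (bin_j, bin_i)
        self.entries[key] = self.entries.get(key, 0.0) + value

    def lookup(self, pos_a: float, pos_b: float) -> float:
        """Contact frequency between two positions, plus pseudocount."""
        i, j = self.bin_of(pos_a), self.bin_of(pos_b)
        key = (i, j) if i <= j else (j, i)
        return self.entries.get(key, 0.0) + self.pseudocount

    def max_entry(self) -> float:
        """Largest stored frequency plus pseudocount (0-entry map -> pc)."""
        base = max(self.entries.values()) if self.entries else 0.0
        return base + self.pseudocount


@dataclass
class DistanceContactModel:
    """Inverse-distance contact estimate (fractal-globule behaviour).

    C(d) = 1 / max(d, min_distance); the clamp keeps the estimate finite
    for self- and near-self contacts. No pseudocount is needed: the
    estimate is strictly positive at every distance.
    """

    min_distance: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")

    def estimate(self, d: float) -> float:
        if d < 0:
            raise ValueError("distance must be non-negative")
        return 1.0 / max(d, self.min_distance)

    def lookup(self, pos_a: float, pos_b: float) -> float:
        if pos_a < 0 or pos_b < 0:
            raise ValueError("negative position")
        return self.estimate(abs(pos_a - pos_b))


def read_contact_triples(
    path,
    resolution: int,
    chrom: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prebinned: bool = False,
) -> ContactMap:
    """Read a sparse contact matrix from whitespace-separated triplets.

    Lines are ``pos1 pos2 value`` (bp positions binned at ``resolution``)
    or, with ``prebinned=True``, ``bin1 bin2 value``. An optional leading
    chromosome column is accepted; inter-chromosomal pairs are skipped with
    a warning. Duplicate (i, j) pairs are summed; storage is symmetric.
    """
    cmap = ContactMap(chrom or "", resolution, {}, pseudocount)
    n_inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) == 3:
                c1 = c2 = None
                p1, p2, val_s = parts
            elif len(parts) == 5:
                c1, p1, c2, p2, val_s = parts
            elif len(parts) == 4:
                c1, p1, p2, val_s = parts
                c2 = c1
            else:
                raise GabcParseError(
                    f"{path}, line {lineno}: expected 3-5 columns"
                )
            if c1 is not None and c1 != c2:
                n_inter += 1
                continue
            if c1 is not None:
                if not cmap.chrom:
                    cmap.chrom = c1
                elif c1 != cmap.chrom:
                    n_inter += 1
                    continue
            value = float(val_s)
            if value < 0:
                raise GabcParseError(
                    f"{path}, line {lineno}: negative frequency {value}"
                )
            if prebinned:
                b1, b2 = int(p1), int(p2)
            else:
                b1, b2 = cmap.bin_of(float(p1)), cmap.bin_of(float(p2))
            cmap.set(b1, b2, value)
    if n_inter:
        warnings.warn(
            f"{path}: skipped {n_inter} inter-chromosomal pair(s)",
            stacklevel=2,
        )
    return cmap


def average_contact_maps(maps: list[ContactMap]) -> ContactMap:
    """Entrywise arithmetic mean of contact maps (missing entries = 0).

    All maps must share chromosome and resolution. The pseudocount of the
    result is the mean of the inputs' pseudocounts.
    """
    if not maps:
        raise ValueError("no contact maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.resolution != first.resolution:
            raise ValueError("resolution mismatch between contact maps")
        if m.chrom != first.chrom:
            raise ValueError("chromosome mismatch between contact maps")
    n = len(maps)
    merged: dict[tuple[int, int], float] = {}
    for m in maps:
        for key, v in m.entries.items():
            merged[key] = merged.get(key, 0.0) + v
    entries = {key: v / n for key, v in merged.items()}
    pc = sum(m.pseudocount for m in maps) / n
    return ContactMap(first.chrom, first.resolution, entries, pc)
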