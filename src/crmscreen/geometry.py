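"""Strand-aware promoter geometry: search regions and signed promoter coordinates.

Two regions drive the screen:

* the **core promoter**: 200 bp upstream of the transcription start site
  (TSS) through the base before the translational start (the A of ATG), in
  transcript orientation;
* the **CRM search space**: 2000 bp upstream of the TSS through the end of
  the 3' UTR, intersected with accessible-chromatin (DHS) intervals.

All genomic coordinates held by :class:`GeneModel` and emitted in
:class:`RegionSet` are 1-based inclusive (GFF3 convention); interval
arithmetic converts internally as needed.

Promoter positions are reported as signed offsets relative to the
translational start with **no position 0**: +1 is the A of ATG, -1 the base
immediately upstream (..., -2, -1, +1, +2, ...).  Off-by-one here corrupts
every downstream report, so the convention is centralised in
:func:`relative_position` / :func:`genomic_position` and property-tested as
a bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneModel",
    "RegionSet",
    "core_promoter_region",
    "crm_search_region",
    "relative_position",
    "genomic_position",
    "merge_intervals",
    "intersect_intervals",
]

CORE_UPSTREAM_DEFAULT = 200
CRM_UPSTREAM_DEFAULT = 2000


@dataclass(frozen=True)
class GeneModel:
    """Coordinate anchors of one gene (1-based genomic positions).

    ``tss`` is the first transcribed base, ``translational_start`` the A of
    the start codon, ``utr3_end`` the last transcribed base, all in genomic
    coordinates; transcript order is ascending on '+' and descending on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    translational_start: int
    utr3_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        order = (self.tss, self.translational_start, self.utr3_end)
        ok = order[0] <= order[1] <= order[2] if self.strand == "+" else order[0] >= order[1] >= order[2]
        if not ok:
            raise ValueError(
                f"{self.gene_id}: coordinates not in transcript order for strand "
                f"{self.strand}: TSS={self.tss}, ATG={self.translational_start}, "
                f"3'UTR end={self.utr3_end}"
            )


@dataclass
class RegionSet:
    """Sorted, non-overlapping 1-based inclusive genomic intervals of one gene."""

    gene_id: str
    purpose: str  # "core" | "crm_search"
    chrom: str
    strand: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, start: int, stop: int) -> bool:
        """Whether [start, stop] lies entirely within a single interval."""
        return any(s <= start and stop <= e for s, e in self.intervals)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if s <= e)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect_intervals(a, b) -> list[tuple[int, int]]:
    """Intersection of two 1-based inclusive interval lists (each merged first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _clip(start: int, end: int, chrom_length: int | None) -> list[tuple[int, int]]:
    start = max(start, 1)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return [(start, end)] if start <= end else []


def core_promoter_region(
    gene: GeneModel,
    upstream_len: int = CORE_UPSTREAM_DEFAULT,
    chrom_length: int | None = None,
) -> RegionSet:
    """TSS - upstream_len through the base before the ATG, transcript orientation.

    The ATG base itself is excluded.  The interval is clipped to chromosome
    bounds; it may be empty when TSS and ATG coincide at a chromosome edge.
    """
    if gene.strand == "+":
        if gene.translational_start < gene.tss:
            raise ValueError(f"{gene.gene_id}: ATG upstream of TSS")
        ivs = _clip(gene.tss - upstream_len, gene.translational_start - 1, chrom_length)
    else:
        if gene.translational_start > gene.tss:
            raise ValueError(f"{gene.gene_id}: ATG upstream of TSS")
        ivs = _clip(gene.translational_start + 1, gene.tss + upstream_len, chrom_length)
    return RegionSet(gene.gene_id, "core", gene.chrom, gene.strand, ivs)


def crm_search_region(
    gene: GeneModel,
    dhs,
    upstream_len: int = CRM_UPSTREAM_DEFAULT,
    chrom_length: int | None = None,
) -> RegionSet:
    """[TSS - upstream_len, 3'UTR end] (transcript orientation) intersected with DHS.

    ``dhs`` is a list of strand-less 1-based inclusive accessible-chromatin
    intervals on the gene's chromosome.  The result may be empty.
    """
    if gene.strand == "+":
        span = _clip(gene.tss - upstream_len, gene.utr3_end, chrom_length)
    else:
        span = _clip(gene.utr3_end, gene.tss + upstream_len, chrom_length)
    ivs = intersect_intervals(span, dhs)
    return RegionSet(gene.gene_id, "crm_search", gene.chrom, gene.strand, ivs)


def relative_position(genomic_pos: int, gene: GeneModel) -> int:
    """Signed offset of a genomic position relative to the translational start.

    +1 is the A of ATG; upstream positions are negative; there is no 0.
    """
    delta = genomic_pos - gene.translational_start
    if gene.strand == "-":
        delta = -delta
    return delta + 1 if delta >= 0 else delta


def genomic_position(offset: int, gene: GeneModel) -> int:
    """Inverse of :func:`relative_position` (offset 0 is invalid)."""
    if offset == 0:
        raise ValueError("offset 0 does not exist in the skip-zero convention")
    delta = offset - 1 if offset > 0 else offset
    if gene.strand == "-":
        delta = -delta
    return gene.translational_start + delta
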