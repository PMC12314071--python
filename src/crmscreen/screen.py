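"""Genome-wide co-occurrence screen for the six-family CRM plus core Y-patch.

A gene is called ``has_crm`` when one passing hit from each of six
transcription-factor families (WRKY, G2-like, MYB-related, DOF, IDD,
bZIP/DPBF) can be selected such that all six lie within a single
contiguous accessible-chromatin interval of the gene's search space
(TSS-2000 through the 3'UTR end, intersected with DHS) and span at most
300 bp.  Family-specific p-value cutoffs apply: WRKY and G2-like hits pass
at p < 1e-3, the other four families at p < 1e-4 (all from a scan run at
the loose 1e-3 threshold).  ``has_y_patch`` requires an orientation-correct
Y-patch in the core promoter (TSS-200 through the base before the ATG);
``has_both`` is their conjunction.

The 300-bp span rule is applied jointly to all six families (one compact
module); ``strict_families_only_window=True`` switches to the literal
alternative where only the four strict families are span-constrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_promoter import Y_PATCH_P_THRESHOLD, count_y_patches, detect_y_patch
from .geometry import GeneModel, RegionSet, core_promoter_region, crm_search_region
from .pwm import MotifHit, build_pwm, reverse_complement, scan_sequence

logger = logging.getLogger("crmscreen")

__all__ = [
    "DEFAULT_FAMILY_P",
    "CRMCall",
    "ScreenResult",
    "EnrichmentResult",
    "label_and_filter_hits",
    "call_crm_windows",
    "gene_screen",
    "enrichment_test",
]

#: Per-family occurrence p-value cutoffs (strict inequality).
DEFAULT_FAMILY_P = {
    "WRKY": 1e-3,
    "G2like": 1e-3,
    "MYBR_B": 1e-4,
    "DOF": 1e-4,
    "IDD": 1e-4,
    "DPBF": 1e-4,
}

REQUIRED_FAMILIES = frozenset(DEFAULT_FAMILY_P)
CRM_WINDOW_BP = 300
SCAN_P_THRESHOLD = 1e-3


@dataclass
class CRMCall:
    """One gene-level co-occurrence event inside accessible chromatin."""

    gene_id: str
    window_start: int  # genomic, 1-based inclusive
    window_end: int
    families_present: frozenset
    supporting_hits: dict[str, MotifHit]  # lowest-p hit per family

    @property
    def span_length(self) -> int:
        return self.window_end - self.window_start + 1


@dataclass
class ScreenResult:
    """Per-gene flags plus summary counts for one screen run."""

    table: pd.DataFrame  # gene_id, has_y_patch, has_crm, has_both, y_patch_count, n_crm_calls
    calls: dict[str, list[CRMCall]] = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, int]:
        t = self.table
        return {
            "n_genes": int(len(t)),
            "n_y_patch": int(t.has_y_patch.sum()),
            "n_crm": int(t.has_crm.sum()),
            "n_both": int(t.has_both.sum()),
        }

    def genes_with_both(self) -> set[str]:
        return set(self.table.loc[self.table.has_both, "gene_id"])

    def crosstab(self, gene_classes: dict[str, set]) -> pd.DataFrame:
        """Cross-tabulation of has_both against named gene classes."""
        rows = []
        both = self.genes_with_both()
        universe = set(self.table.gene_id)
        for name, members in gene_classes.items():
            members = members & universe
            rows.append(
                {
                    "class": name,
                    "class_size": len(members),
                    "has_both_in_class": len(both & members),
                    "has_both_total": len(both),
                }
            )
        return pd.DataFrame(rows)


def label_and_filter_hits(
    hits: list[MotifHit],
    family_map,
    per_family_p: dict[str, float] = DEFAULT_FAMILY_P,
) -> list[MotifHit]:
    """Attach families and keep hits passing their family's strict cutoff.

    Hits whose motif maps to no screened family are dropped with a warning.
    """
    out: list[MotifHit] = []
    dropped_unmapped = 0
    for h in hits:
        fam = h.family or family_map.family_of(h.motif_id)
        if fam not in per_family_p:
            dropped_unmapped += 1
            continue
        if h.p_value < per_family_p[fam]:
            if h.family != fam:
                h = MotifHit(
                    motif_id=h.motif_id,
                    family=fam,
                    sequence_name=h.sequence_name,
                    start=h.start,
                    stop=h.stop,
                    strand=h.strand,
                    score=h.score,
                    p_value=h.p_value,
                    matched_sequence=h.matched_sequence,
                )
            out.append(h)
    if dropped_unmapped:
        logger.warning(
            "label_and_filter_hits: %d hits without a screened family dropped", dropped_unmapped
        )
    return out


def _anchored_calls(
    hits: list[MotifHit], required: frozenset, window_bp: int, gene_id: str
) -> list[CRMCall]:
    """Candidate calls from one contiguous interval's family-labelled hits."""
    hits = sorted(hits, key=lambda h: (h.start, h.stop, h.motif_id))
    calls: list[CRMCall] = []
    for a_idx, anchor in enumerate(hits):
        lo = anchor.start
        hi = lo + window_bp - 1
        in_range = [h for h in hits[a_idx:] if h.start >= lo and h.stop <= hi]
        by_family: dict[str, list[MotifHit]] = {}
        for h in in_range:
            by_family.setdefault(h.family, []).append(h)
        if not required <= set(by_family):
            continue
        # minimal span anchored at this leftmost hit: each required family
        # contributes its earliest-ending hit
        window_end = max(min(h.stop for h in by_family[f]) for f in required)
        support = {
            f: min(
                (h for h in by_family[f] if h.stop <= window_end),
                key=lambda h: (h.p_value, h.start, h.motif_id),
            )
            for f in required
        }
        present = frozenset(f for f, hs in by_family.items() if any(h.stop <= window_end for h in hs))
        calls.append(
            CRMCall(
                gene_id=gene_id,
                window_start=lo,
                window_end=window_end,
                families_present=present,
                supporting_hits=support,
            )
        )
    return calls


def call_crm_windows(
    hits: list[MotifHit],
    required_families: frozenset = REQUIRED_FAMILIES,
    window_bp: int = CRM_WINDOW_BP,
    regions: RegionSet | None = None,
    gene_id: str = "",
) -> list[CRMCall]:
    """Six-family co-occurrence calls within ``window_bp``, one per locus.

    A call exists iff one passing hit per required family can be chosen with
    joint span (max stop - min start + 1) <= ``window_bp``, all inside one
    contiguous interval of ``regions`` (no bridging across accessibility
    gaps).  Overlapping candidate calls are reduced to the minimal-span call
    per locus (ties broken by leftmost start).
    """
    if regions is not None:
        groups = [
            [h for h in hits if s <= h.start and h.stop <= e] for s, e in regions.intervals
        ]
        gene_id = gene_id or regions.gene_id
    else:
        groups = [list(hits)]
    candidates: list[CRMCall] = []
    for group in groups:
        candidates.extend(_anchored_calls(group, required_families, window_bp, gene_id))
    # minimal-span call per locus: greedy accept by (span, start), skip overlaps
    candidates.sort(key=lambda c: (c.span_length, c.window_start, c.window_end))
    accepted: list[CRMCall] = []
    for c in candidates:
        if all(c.window_end < a.window_start or c.window_start > a.window_end for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda c: c.window_start)
    return accepted


def _extract(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    return genome[chrom][start - 1 : end]


def _scan_pwms_in_regions(
    genome: dict[str, str],
    regions: RegionSet,
    pwms: list,
    families: dict[str, str],
    p_threshold: float,
) -> list[MotifHit]:
    """Scan PWMs over each region interval; hits in genomic coordinates."""
    hits: list[MotifHit] = []
    for s, e in regions.intervals:
        subseq = _extract(genome, regions.chrom, s, e)
        for pwm in pwms:
            for h in scan_sequence(
                subseq,
                pwm,
                p_threshold=p_threshold,
                strands="both",
                sequence_name=regions.chrom,
                family=families.get(pwm.motif_id, ""),
            ):
                hits.append(
                    MotifHit(
                        motif_id=h.motif_id,
                        family=h.family,
                        sequence_name=regions.chrom,
                        start=h.start + s - 1,
                        stop=h.stop + s - 1,
                        strand=h.strand,
                        score=h.score,
                        p_value=h.p_value,
                        matched_sequence=h.matched_sequence,
                    )
                )
    return hits


def gene_screen(
    genes: list[GeneModel],
    genome: dict[str, str],
    dhs: dict[str, list[tuple[int, int]]],
    motif_library,
    family_map,
    y_patch_model=None,
    per_family_p: dict[str, float] = DEFAULT_FAMILY_P,
    window_bp: int = CRM_WINDOW_BP,
    core_upstream: int = 200,
    crm_upstream: int = 2000,
    y_patch_p: float = Y_PATCH_P_THRESHOLD,
    scan_p: float = SCAN_P_THRESHOLD,
) -> ScreenResult:
    """The full co-occurrence screen over a set of gene models.

    Per gene: the core promoter (TSS-``core_upstream`` to the base before
    ATG) is scanned for orientation-correct Y-patches; the accessible search
    space (TSS-``crm_upstream`` to 3'UTR end, intersected with DHS) is
    scanned with the family motif library at the loose threshold, hits are
    filtered by per-family cutoffs, and six-family windows are called.
    Deterministic given identical inputs.
    """
    families = {e.motif_id: (e.family or family_map.family_of(e.motif_id)) for e in motif_library}
    pwms = [
        build_pwm(e.matrix, motif_id=e.motif_id)
        for e in motif_library
        if families[e.motif_id] in per_family_p
    ]
    required = frozenset(per_family_p)

    rows = []
    calls_by_gene: dict[str, list] = {}
    for gene in genes:
        if gene.chrom not in genome:
            logger.warning("gene %s: chromosome %s missing from genome; skipped", gene.gene_id, gene.chrom)
            continue
        chrom_len = len(genome[gene.chrom])

        core = core_promoter_region(gene, upstream_len=core_upstream, chrom_length=chrom_len)
        y_hits = []
        for s, e in core.intervals:
            seq = _extract(genome, gene.chrom, s, e)
            if gene.strand == "-":
                seq = reverse_complement(seq)
            y_hits.extend(
                detect_y_patch(seq, y_patch_model, p_threshold=y_patch_p, sequence_name=gene.gene_id)
            )
        has_y = bool(y_hits)

        search = crm_search_region(
            gene, dhs.get(gene.chrom, []), upstream_len=crm_upstream, chrom_length=chrom_len
        )
        raw = _scan_pwms_in_regions(genome, search, pwms, families, scan_p)
        passing = label_and_filter_hits(raw, family_map, per_family_p)
        calls = call_crm_windows(
            passing, required, window_bp=window_bp, regions=search, gene_id=gene.gene_id
        )
        calls_by_gene[gene.gene_id] = calls

        rows.append(
            {
                "gene_id": gene.gene_id,
                "has_y_patch": has_y,
                "has_crm": bool(calls),
                "has_both": has_y and bool(calls),
                "y_patch_count": count_y_patches(y_hits),
                "n_crm_calls": len(calls),
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "has_y_patch", "has_crm", "has_both", "y_patch_count", "n_crm_calls"]
    )
    result = ScreenResult(table=table, calls=calls_by_gene)
    logger.info("gene_screen: %s", result.summary)
    return result


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # [[a, b], [c, d]]
    odds_ratio: float  # sample OR ad/bc; inf/nan for degenerate tables
    p_value: float
    degenerate: bool = False


def enrichment_test(flag: set, klass: set, universe: set) -> EnrichmentResult:
    """Fisher's exact two-sided test of flagged genes against a gene class.

    2x2 table: a = flag&class, b = flag only, c = class only, d = neither.
    The sample odds ratio is ad/bc (inf if bc = 0 with ad > 0, nan for the
    fully degenerate 0/0 case, flagged via ``degenerate``).
    """
    if not universe:
        raise ValueError("empty universe")
    if not (flag <= universe and klass <= universe):
        raise ValueError("flag and class must be subsets of the universe")
    a = len(flag & klass)
    b = len(flag - klass)
    c = len(klass - flag)
    d = len(universe - flag - klass)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
        degenerate = False
    elif a * d > 0:
        odds, degenerate = float("inf"), True
    else:
        odds, degenerate = float("nan"), True
    return EnrichmentResult(table=((a, b), (c, d)), odds_ratio=odds, p_value=float(p), degenerate=degenerate)
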