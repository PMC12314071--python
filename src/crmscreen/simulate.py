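"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators, all driven by one seed (independent sub-streams per
stage, so enlarging one simulation never perturbs another):

* :func:`simulate_genome` - background promoter/gene sequence at a
  configurable base composition with planted six-family motif sextets
  (bounded span, inside accessible chromatin), orientation-correct
  Y-patches in core promoters, a DHS track, gene models, and a truth table;
* :func:`simulate_expression` - TPM matrices over the 7-stage, 3-4
  replicate, three-cell-type design plus differential-expression summary
  tables with known class membership relative to the compound filters,
  including the strict-inequality boundary cases (log2FC exactly 2.0, TPM
  exactly 1.0);
* :func:`simulate_kinetics` - linear plate-reader time courses (20 cycles,
  2-min spacing) with known true rates, a ten-point standard curve, and
  Gaussian noise.

Planted motif instances are family consensus strings of the synthetic
motif library (sharp 97:1 count matrices), which guarantees their
occurrence p-values sit below the per-family cutoffs; the nine-base length
is chosen so that under a uniform background only the exact consensus
passes the strict 1e-4 family cutoff (single-mismatch words carry
p ~= 1.07e-4), keeping chance co-occurrence calls rare in background
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_promoter import default_y_patch_pwm
from .expression import ExpressionTable
from .geometry import GeneModel
from .io import FamilyMap, MotifEntry, MotifLibrary, write_bed, write_family_map, write_fasta, write_motifs
from .pwm import reverse_complement
from .reporter import KineticSeries

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedExpression",
    "SimulatedKinetics",
    "FAMILY_CONSENSUS",
    "build_family_library",
    "build_polII_library",
    "simulate_genome",
    "simulate_expression",
    "simulate_kinetics",
    "write_genome_fixtures",
]

#: Consensus strings of the synthetic six-family motif library (length 9).
FAMILY_CONSENSUS = {
    "WRKY": "TTTGACTTT",  # W-box core TTGAC
    "G2like": "CAGATTCTC",  # GATT-type GLK site
    "MYBR_B": "TAACGGTTC",  # MYB-related AACGG core
    "DOF": "AAAGCAAAG",  # AAAG-rich DOF site
    "IDD": "TTTGTCGTT",  # TGTCG-type IDD site
    "DPBF": "CCACGTGTC",  # ACGT-core bZIP/ABRE-like site
}

#: Synthetic POLII core-promoter element consensus strings.
POLII_CONSENSUS = {
    "MTE": "CGAGCGGAAC",
    "BREu": "GGGCGCCTC",
    "DCE_S_I": "CTTCGTCC",
}

STRICT_FAMILIES = ("MYBR_B", "DOF", "IDD", "DPBF")

CATEGORIES = ("both", "crm_only", "ypatch_only", "five_family", "neither")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, fixed by one seed."""

    seed: int = 0
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (2000, 6000)
    gc_content: float = 0.40
    category_fractions: dict = field(
        default_factory=lambda: {
            "both": 0.40,
            "crm_only": 0.15,
            "ypatch_only": 0.15,
            "five_family": 0.10,
            "neither": 0.20,
        }
    )
    crm_span_limit: int = 280
    dhs_mode: str = "cover-plants"  # cover-plants | exclude-plants | everything
    dhs_margin: int = 20
    flank: int = 2500  # contig sequence on each side of a gene
    # expression
    n_expression_genes: int = 60
    bs_log2fc_mean: float = 3.0
    bs_log2fc_sd: float = 0.5
    # kinetics
    kinetic_rates: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 12.5)  # nmol 4-MU/min/mg
    lines_per_construct: int = 6
    kinetic_noise_sd: float = 20.0  # AU
    curve_slope: float = 800.0  # AU per nmol 4-MU
    curve_intercept: float = 30.0

    def __post_init__(self):
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions must sum to 1 (got {total})")
        unknown = set(self.category_fractions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent sub-stream per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stage)]))


def _sharp_counts(consensus: str, hit: float = 97.0, miss: float = 1.0) -> np.ndarray:
    mat = np.full((len(consensus), 4), miss)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = hit
    return mat


def build_family_library() -> tuple[MotifLibrary, FamilyMap]:
    """Synthetic six-family motif library (one sharp PWM per family)."""
    entries = []
    fm = FamilyMap()
    for family, consensus in FAMILY_CONSENSUS.items():
        motif_id = f"{family}_syn1"
        entries.append(MotifEntry(motif_id=motif_id, matrix=_sharp_counts(consensus), family=family))
        fm[motif_id] = family
    return MotifLibrary(entries), fm


def build_polII_library() -> tuple[MotifLibrary, FamilyMap]:
    """Synthetic POLII core-promoter element library (incl. Y-patch PWM counts)."""
    entries = []
    fm = FamilyMap()
    for family, consensus in POLII_CONSENSUS.items():
        motif_id = f"{family}_syn1"
        entries.append(MotifEntry(motif_id=motif_id, matrix=_sharp_counts(consensus), family=family))
        fm[motif_id] = family
    ypwm = default_y_patch_pwm()
    entries.append(
        MotifEntry(motif_id="Ypatch_syn1", matrix=np.tile(np.array([5.0, 45.0, 5.0, 45.0]), (12, 1)), family="Ypatch")
    )
    fm["Ypatch_syn1"] = "Ypatch"
    return MotifLibrary(entries), fm


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _to_str(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)


def _plant(codes: np.ndarray, pos0: int, word: str) -> None:
    for i, base in enumerate(word):
        codes[pos0 + i] = "ACGT".index(base)


def _random_y_patch(rng: np.random.Generator, length: int = 12) -> str:
    word = ["C" if rng.random() < 0.5 else "T" for _ in range(length)]
    for i in (2, 6, 10):  # guarantee a C inside every 8-bp sub-window
        word[i] = "C"
    return "".join(word)


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    dhs: dict[str, list[tuple[int, int]]]
    truth: pd.DataFrame
    library: MotifLibrary
    family_map: FamilyMap
    config: SimulationConfig


def _category_assignment(config: SimulationConfig) -> list[str]:
    """Deterministic category counts: floors plus largest-remainder top-up."""
    n = config.n_genes
    raw = {c: config.category_fractions.get(c, 0.0) * n for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    cats: list[str] = []
    for c in CATEGORIES:
        cats.extend([c] * counts[c])
    return cats


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Genome FASTA + gene models + DHS + truth table with planted signals.

    Each gene sits on its own contig with ``config.flank`` bp on either
    side, which keeps every gene's regulatory span (TSS-2000 to 3'UTR end)
    free of its neighbours' planted elements.  Genes alternate strands.
    Categories plant: ``both`` = six-family sextet (span <= limit, inside a
    DHS) plus an orientation-correct core Y-patch; ``crm_only`` /
    ``ypatch_only`` = one of the two; ``five_family`` = Y-patch plus a
    sextet missing one strict family (negative control for the six-family
    requirement); ``neither`` = pure background.
    """
    rng = config.rng(11)
    library, family_map = build_family_library()
    categories = _category_assignment(config)
    rng.shuffle(categories)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    dhs: dict[str, list[tuple[int, int]]] = {}
    rows = []
    lo_len, hi_len = config.gene_length_range
    min_required = 1200
    if lo_len < min_required:
        raise ValueError(f"gene length range must allow >= {min_required} bp genes")
    missing_cycle = 0

    for g, category in enumerate(categories):
        gene_id = f"gene{g + 1:04d}"
        chrom = f"contig{g + 1:04d}"
        gene_len = int(rng.integers(lo_len, hi_len + 1))
        strand = "+" if g % 2 == 0 else "-"
        contig_len = config.flank * 2 + gene_len
        codes = _random_sequence(rng, contig_len, config.gc_content)

        gene_start = config.flank + 1  # 1-based
        gene_end = config.flank + gene_len
        utr5_len = int(rng.integers(150, 401))
        utr3_len = int(rng.integers(150, 301))
        if strand == "+":
            tss, atg, utr3_end = gene_start, gene_start + utr5_len, gene_end
        else:
            tss, atg, utr3_end = gene_end, gene_end - utr5_len, gene_start
        gene = GeneModel(gene_id, chrom, strand, tss, atg, utr3_end)

        plant_crm = category in ("both", "crm_only", "five_family")
        plant_ypatch = category in ("both", "ypatch_only", "five_family")
        missing_family = ""
        block = (0, 0)

        if plant_crm:
            families = list(FAMILY_CONSENSUS)
            if category == "five_family":
                missing_family = STRICT_FAMILIES[missing_cycle % len(STRICT_FAMILIES)]
                missing_cycle += 1
                families.remove(missing_family)
            block = _plant_sextet(codes, rng, gene, config, families)
        if plant_ypatch:
            _plant_y_patch(codes, rng, gene)

        genome[chrom] = _to_str(codes)
        genes.append(gene)
        dhs[chrom] = _dhs_for_gene(rng, gene, config, block if plant_crm else None, contig_len)
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "category": category,
                "strand": strand,
                "crm_planted": plant_crm,
                "ypatch_planted": plant_ypatch,
                "n_families_planted": 0 if not plant_crm else (5 if category == "five_family" else 6),
                "missing_family": missing_family,
                "block_start": block[0],
                "block_end": block[1],
            }
        )

    truth = pd.DataFrame(rows)
    return SimulatedGenome(genome, genes, dhs, truth, family_map.apply(library), family_map, config)


def _transcript_interval(gene: GeneModel) -> tuple[int, int]:
    a, b = gene.tss, gene.utr3_end
    return (a, b) if a <= b else (b, a)


def _plant_sextet(codes, rng, gene: GeneModel, config: SimulationConfig, families) -> tuple[int, int]:
    """Plant one consensus per family within <= span limit; genomic 1-based block."""
    words = [FAMILY_CONSENSUS[f] for f in families]
    order = rng.permutation(len(words))
    words = [words[i] for i in order]
    total_len = sum(len(w) for w in words)
    slack = config.crm_span_limit - total_len
    n_gaps = len(words) - 1
    gaps = rng.integers(3, max(4, slack // n_gaps), size=n_gaps) if n_gaps else []
    span = total_len + int(np.sum(gaps))

    lo, hi = _transcript_interval(gene)
    # keep the block inside the gene body, clear of the core promoter
    if gene.strand == "+":
        body_lo, body_hi = gene.translational_start + 50, hi - 50
    else:
        body_lo, body_hi = lo + 50, gene.translational_start - 50
    upstream = rng.random() < 0.4
    if upstream:
        if gene.strand == "+":
            region_lo, region_hi = gene.tss - 1800, gene.tss - 300 - span
        else:
            region_lo, region_hi = gene.tss + 300, gene.tss + 1800 - span
    else:
        region_lo, region_hi = body_lo, body_hi - span
    if region_hi <= region_lo:
        region_lo, region_hi = body_lo, body_hi - span
    if region_hi <= region_lo:
        raise ValueError(f"{gene.gene_id}: gene too short to plant a {span}-bp module")
    start = int(rng.integers(region_lo, region_hi + 1))  # 1-based genomic

    pos = start
    for i, word in enumerate(words):
        oriented = word if rng.random() < 0.5 else reverse_complement(word)
        _plant(codes, pos - 1, oriented)
        pos += len(word) + (int(gaps[i]) if i < len(gaps) else 0)
    return (start, start + span - 1)


def _plant_y_patch(codes, rng, gene: GeneModel) -> None:
    """Orientation-correct Y-patch in the core promoter (TSS-200 to ATG-1)."""
    word = _random_y_patch(rng)
    if gene.strand == "+":
        lo, hi = gene.tss - 150, gene.translational_start - 1 - len(word)
        pos = int(rng.integers(lo, hi + 1))
        _plant(codes, pos - 1, word)
    else:
        lo, hi = gene.translational_start + 1, gene.tss + 150 - len(word)
        pos = int(rng.integers(lo, hi + 1))
        _plant(codes, pos - 1, reverse_complement(word))


def _dhs_for_gene(rng, gene: GeneModel, config: SimulationConfig, block, contig_len: int):
    """Accessible-chromatin intervals for one contig, per coverage mode."""
    mode = config.dhs_mode
    if mode == "everything":
        return [(1, contig_len)]
    intervals: list[tuple[int, int]] = []
    lo, hi = _transcript_interval(gene)
    if block is not None and mode == "cover-plants":
        intervals.append((max(1, block[0] - config.dhs_margin), min(contig_len, block[1] + config.dhs_margin)))
    # one random accessible interval per gene, away from the planted block
    for _ in range(8):
        s = int(rng.integers(max(1, lo - 1500), hi - 400))
        e = s + 400
        if block is None or e < block[0] - 50 or s > block[1] + 50:
            intervals.append((s, e))
            break
    return sorted(intervals)


def write_genome_fixtures(sim: SimulatedGenome, outdir) -> dict[str, Path]:
    """Write FASTA/GFF3/BED/motifs/family-map/truth files for a simulated genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "bed": outdir / "dhs.bed",
        "motifs": outdir / "motifs.jaspar",
        "family_map": outdir / "family_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(sim.genome, paths["fasta"])
    _write_gff3(sim, paths["gff3"])
    write_bed(sim.dhs, paths["bed"])
    write_motifs(sim.library, paths["motifs"], dialect="jaspar_pfm")
    write_family_map(sim.family_map, paths["family_map"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _write_gff3(sim: SimulatedGenome, path) -> None:
    lines = ["##gff-version 3"]
    for gene in sim.genes:
        lo, hi = _transcript_interval(gene)
        gid, mid = gene.gene_id, gene.gene_id + ".1"
        if gene.strand == "+":
            utr5 = (gene.tss, gene.translational_start - 1)
            cds_end = hi - (hi - gene.translational_start) // 4  # arbitrary split
            cds = (gene.translational_start, cds_end)
            utr3 = (cds_end + 1, hi)
        else:
            utr5 = (gene.translational_start + 1, gene.tss)
            cds_start = lo + (gene.translational_start - lo) // 4
            cds = (cds_start, gene.translational_start)
            utr3 = (lo, cds_start - 1)
        feats = [
            ("gene", lo, hi, f"ID={gid}"),
            ("mRNA", lo, hi, f"ID={mid};Parent={gid}"),
            ("five_prime_UTR", utr5[0], utr5[1], f"ID={mid}.utr5;Parent={mid}"),
            ("CDS", cds[0], cds[1], f"ID={mid}.cds;Parent={mid}"),
            ("three_prime_UTR", utr3[0], utr3[1], f"ID={mid}.utr3;Parent={mid}"),
        ]
        for ftype, s, e, attrs in feats:
            lines.append(
                "\t".join([gene.chrom, "crmscreen_sim", ftype, str(s), str(e), ".", gene.strand, ".", attrs])
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class SimulatedExpression:
    expression: ExpressionTable
    de_stats: pd.DataFrame
    truth: pd.DataFrame


#: stages 1-3 carry 4 replicates, stages 4-7 carry 3 (mirrors a 3-4 rep design)
STAGE_REPLICATES = {1: 4, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3, 7: 3}

_VIOLATION_MODES = ("log2fc_at_boundary", "padj_high", "fdr_high", "bs_v_low", "log2fc_low", "missing_padj")


def simulate_expression(config: SimulationConfig, genome_truth: pd.DataFrame | None = None) -> SimulatedExpression:
    """TPM and DE summary tables with known filter-class membership.

    When a genome truth table is supplied its genes are reused (genes whose
    category is ``both`` are bundle-sheath specific with probability 0.6,
    others 0.1, giving the screen something to be enriched against);
    otherwise ``config.n_expression_genes`` synthetic genes are drawn.
    Three boundary genes are always appended: TPM exactly 1.0 everywhere
    (fails the expressed filter), TPM above 1 in only 2 samples of a stage
    (fails), and log2FC(BS/M) exactly 2.0 (fails the specificity filter).
    """
    rng = config.rng(22)
    if genome_truth is not None:
        gene_ids = list(genome_truth["gene_id"])
        bs_prob = np.where(genome_truth["category"].eq("both"), 0.6, 0.1)
        bs_specific = rng.random(len(gene_ids)) < bs_prob
    else:
        gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_expression_genes)]
        bs_specific = rng.random(len(gene_ids)) < 0.3
    expressed = np.ones(len(gene_ids), dtype=bool)
    expressed[rng.random(len(gene_ids)) < 0.15] = False
    bs_specific = bs_specific & expressed

    boundary = [
        ("edge_tpm_exactly_one", False, False),
        ("edge_two_samples_over", False, False),
        ("edge_log2fc_exactly_two", True, False),
    ]
    gene_ids = gene_ids + [b[0] for b in boundary]
    expressed = np.concatenate([expressed, [b[1] for b in boundary]])
    bs_specific = np.concatenate([bs_specific, [b[2] for b in boundary]])

    samples, meta_rows = [], []
    for ct in ("BS", "M", "V"):
        for stage, n_rep in STAGE_REPLICATES.items():
            for rep in range(1, n_rep + 1):
                name = f"{ct}_s{stage}_r{rep}"
                samples.append(name)
                meta_rows.append({"sample": name, "cell_type": ct, "stage": stage, "replicate": rep})
    meta = pd.DataFrame(meta_rows).set_index("sample")

    tpm = np.zeros((len(gene_ids), len(samples)))
    for i, gid in enumerate(gene_ids):
        if gid == "edge_tpm_exactly_one":
            tpm[i, :] = 1.0
            continue
        if gid == "edge_two_samples_over":
            tpm[i, :] = rng.uniform(0.0, 0.8, size=len(samples))
            stage1 = [j for j, s in enumerate(samples) if meta.iloc[j]["stage"] == 1][:2]
            tpm[i, stage1] = 5.0  # only two samples above threshold: still not expressed
            continue
        if expressed[i]:
            base = rng.uniform(5, 80)
            vals = base * rng.lognormal(0, 0.25, size=len(samples))
            if bs_specific[i]:
                is_bs = meta["cell_type"].eq("BS").to_numpy()
                vals = np.where(is_bs, vals * 8.0, vals)
            tpm[i, :] = vals
        else:
            tpm[i, :] = rng.uniform(0.0, 0.9, size=len(samples))
    expr = ExpressionTable(tpm=pd.DataFrame(tpm, index=gene_ids, columns=samples), meta=meta)

    de_rows = []
    mode_cycle = 0
    for i, gid in enumerate(gene_ids):
        if gid == "edge_log2fc_exactly_two":
            de_rows.append({"gene_id": gid, "log2fc_bs_m": 2.0, "padj_bs_m": 1e-4, "fdr_bs_m": 1e-4, "log2fc_bs_v": 0.5})
            continue
        if bs_specific[i]:
            fc = 0.0
            while fc <= 2.05:
                fc = rng.normal(config.bs_log2fc_mean, config.bs_log2fc_sd)
            de_rows.append(
                {
                    "gene_id": gid,
                    "log2fc_bs_m": fc,
                    "padj_bs_m": rng.uniform(1e-6, 0.009),
                    "fdr_bs_m": rng.uniform(1e-6, 0.009),
                    "log2fc_bs_v": rng.uniform(0.0, 3.0),
                }
            )
        else:
            mode = _VIOLATION_MODES[mode_cycle % len(_VIOLATION_MODES)]
            mode_cycle += 1
            row = {
                "gene_id": gid,
                "log2fc_bs_m": rng.uniform(2.5, 5.0),
                "padj_bs_m": rng.uniform(1e-6, 0.009),
                "fdr_bs_m": rng.uniform(1e-6, 0.009),
                "log2fc_bs_v": rng.uniform(0.0, 3.0),
            }
            if mode == "log2fc_at_boundary":
                row["log2fc_bs_m"] = 2.0
            elif mode == "padj_high":
                row["padj_bs_m"] = rng.uniform(0.02, 0.8)
            elif mode == "fdr_high":
                row["fdr_bs_m"] = rng.uniform(0.02, 0.8)
            elif mode == "bs_v_low":
                row["log2fc_bs_v"] = rng.uniform(-3.0, -0.6)
            elif mode == "log2fc_low":
                row["log2fc_bs_m"] = rng.uniform(-2.0, 1.5)
            elif mode == "missing_padj":
                row["padj_bs_m"] = np.nan
            de_rows.append(row)
    de = pd.DataFrame(de_rows)

    truth = pd.DataFrame({"gene_id": gene_ids, "is_expressed": expressed, "is_bs_specific": bs_specific})
    return SimulatedExpression(expression=expr, de_stats=de, truth=truth)


# ---------------------------------------------------------------------------
# Kinetics


@dataclass
class SimulatedKinetics:
    standards: pd.DataFrame  # conc, fluorescence
    series: list[KineticSeries]
    truth: pd.DataFrame  # line_id, construct_id, true_rate, protein_mg


def simulate_kinetics(config: SimulationConfig) -> SimulatedKinetics:
    """Linear MUG kinetics with known rates: 20 cycles at 2-min spacing.

    fluorescence(t) = intercept + curve_slope * (rate * protein_mg * t) + N(0, sd),
    with a ten-standard curve spanning the assay's dynamic range.  With
    ``kinetic_noise_sd = 0`` the pipeline recovers the true rates exactly.
    """
    rng = config.rng(33)
    if any(r <= 0 for r in config.kinetic_rates):
        raise ValueError("kinetic rates must be positive")
    times = np.arange(20) * 2.0  # minutes
    max_nmol = max(config.kinetic_rates) * 0.15 * times[-1]
    concs = np.linspace(0.0, max(1.0, max_nmol), 10)
    std_fluo = config.curve_intercept + config.curve_slope * concs
    if config.kinetic_noise_sd > 0:
        std_fluo = std_fluo + rng.normal(0, config.kinetic_noise_sd, size=len(concs))
    standards = pd.DataFrame({"conc": concs, "fluorescence": std_fluo})

    series: list[KineticSeries] = []
    truth_rows = []
    for ci, rate in enumerate(config.kinetic_rates):
        construct = f"construct{ci + 1}"
        for li in range(config.lines_per_construct):
            line_id = f"{construct}_line{li + 1}"
            protein = float(rng.uniform(0.05, 0.15))
            for dup in ("A", "B"):
                fluo = config.curve_intercept + config.curve_slope * (rate * protein * times)
                if config.kinetic_noise_sd > 0:
                    fluo = fluo + rng.normal(0, config.kinetic_noise_sd, size=len(times))
                series.append(
                    KineticSeries(
                        line_id=line_id,
                        construct_id=construct,
                        duplicate_id=dup,
                        times_min=times.copy(),
                        fluorescence=fluo,
                        protein_mg=protein,
                    )
                )
            truth_rows.append(
                {"line_id": line_id, "construct_id": construct, "true_rate": rate, "protein_mg": protein}
            )
    return SimulatedKinetics(standards=standards, series=series, truth=pd.DataFrame(truth_rows))


def write_kinetics_fixtures(sim: SimulatedKinetics, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sim.series:
        for t, f in zip(s.times_min, s.fluorescence):
            rows.append(
                {
                    "line_id": s.line_id,
                    "construct_id": s.construct_id,
                    "duplicate": s.duplicate_id,
                    "time_min": t,
                    "fluorescence": f,
                    "protein_mg": s.protein_mg,
                }
            )
    paths = {
        "kinetics": outdir / "kinetics.tsv",
        "standards": outdir / "standards.tsv",
        "truth": outdir / "kinetics_truth.tsv",
    }
    pd.DataFrame(rows).to_csv(paths["kinetics"], sep="\t", index=False)
    sim.standards.to_csv(paths["standards"], sep="\t", index=False)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
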