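"""Readers and writers for the formats the pipeline touches.

FASTA and motif parsing are delegated to Biopython, gene models to
``gffutils``; this module adds the validation and coordinate conventions
the pipeline relies on.  Internal arithmetic is 0-based half-open where it
matters, but every file-facing coordinate in this package is 1-based
inclusive (GFF3 convention), except BED which is read/written 0-based
half-open per the BED standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .geometry import GeneModel
from .pwm import MotifHit

logger = logging.getLogger("crmscreen")

__all__ = [
    "MotifEntry",
    "MotifLibrary",
    "FamilyMap",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "read_bed",
    "write_bed",
    "read_motifs",
    "write_motifs",
    "read_family_map",
    "write_family_map",
    "write_hits_tsv",
    "read_hits_tsv",
]

_ALLOWED = set("ACGTN")

HIT_COLUMNS = [
    "motif_id",
    "family",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p_value",
    "matched_sequence",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Named sequences, upper-cased, alphabet restricted to ACGTN.

    Names are the first whitespace-delimited token of the header.  Duplicate
    names and empty files are errors; a disallowed character is reported with
    its 1-based position.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise ValueError(f"duplicate sequence name {name!r} in {path}")
        seq = str(rec.seq).upper()
        bad = [i for i, c in enumerate(seq) if c not in _ALLOWED]
        if bad:
            raise ValueError(
                f"sequence {name!r}: disallowed character {seq[bad[0]]!r} at position {bad[0] + 1}"
            )
        seqs[name] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    logger.info("read_fasta: %d sequences from %s", len(seqs), path)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)


def read_gene_models(path, isoform: str = "longest") -> list[GeneModel]:
    """One :class:`GeneModel` per gene from a GFF3 file.

    The primary transcript per gene is the longest mRNA (``isoform="first"``
    keeps file order instead).  TSS is the transcript 5' end, the
    translational start the first CDS base in transcript orientation, and
    the 3'UTR end the transcript 3' end.  mRNAs without CDS are skipped with
    a warning; inverted coordinates are an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    out: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            if mrna.start > mrna.end:
                raise ValueError(f"{mrna.id}: inverted coordinates {mrna.start} > {mrna.end}")
            cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            if not cds:
                logger.warning("mRNA %s of gene %s has no CDS; skipped", mrna.id, gene.id)
                continue
            candidates.append((mrna, cds))
        if not candidates:
            logger.warning("gene %s has no coding mRNA; skipped", gene.id)
            continue
        if isoform == "longest":
            mrna, cds = max(candidates, key=lambda mc: mc[0].end - mc[0].start)
        else:
            mrna, cds = candidates[0]
        if mrna.strand == "+":
            tss, atg, utr3 = mrna.start, cds[0].start, mrna.end
        elif mrna.strand == "-":
            tss, atg, utr3 = mrna.end, cds[-1].end, mrna.start
        else:
            raise ValueError(f"mRNA {mrna.id}: strand must be + or -")
        out.append(
            GeneModel(
                gene_id=gene.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                tss=tss,
                translational_start=atg,
                utr3_end=utr3,
            )
        )
    logger.info("read_gene_models: %d gene models from %s", len(out), path)
    return out


# ---------------------------------------------------------------------------
# BED (DHS intervals)


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """BED3+ intervals as 1-based inclusive tuples per chromosome.

    BED is 0-based half-open; intervals are converted on read and treated as
    strand-less.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with < 3 columns: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"empty/inverted BED interval: {line!r}")
            out.setdefault(chrom, []).append((start + 1, end))
            n += 1
    logger.info("read_bed: %d intervals on %d chromosomes from %s", n, len(out), path)
    return out


def write_bed(intervals_by_chrom: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals_by_chrom):
            for start, end in sorted(intervals_by_chrom[chrom]):
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ---------------------------------------------------------------------------
# Motif libraries


@dataclass
class MotifEntry:
    motif_id: str
    matrix: np.ndarray  # L x 4 over A,C,G,T; counts or probabilities
    family: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: empty matrix")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.motif_id}: negative matrix entries")
        if np.any(self.matrix.sum(axis=1) == 0):
            raise ValueError(f"{self.motif_id}: all-zero row")


@dataclass
class MotifLibrary:
    entries: list[MotifEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.motif_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate motif ids in library: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, motif_id: str) -> MotifEntry:
        for e in self.entries:
            if e.motif_id == motif_id:
                return e
        raise KeyError(motif_id)

    def ids(self) -> list[str]:
        return [e.motif_id for e in self.entries]


class FamilyMap(dict):
    """Total map motif_id -> family; unmapped motifs fall back to 'unassigned'."""

    UNASSIGNED = "unassigned"

    def family_of(self, motif_id: str) -> str:
        return self.get(motif_id, self.UNASSIGNED)

    def apply(self, library: MotifLibrary) -> MotifLibrary:
        """New library with family labels filled in from this map."""
        return MotifLibrary(
            [MotifEntry(e.motif_id, e.matrix.copy(), self.family_of(e.motif_id)) for e in library]
        )


def _matrix_from_bio(motif) -> np.ndarray:
    counts = motif.counts
    return np.array([[counts[b][i] for b in "ACGT"] for i in range(motif.length)], dtype=float)


def read_motifs(path, dialect: str = "jaspar_pfm") -> MotifLibrary:
    """Motif library from a JASPAR PFM or MEME-minimal file.

    JASPAR counts are preserved exactly.  MEME-minimal stores probabilities;
    they are kept as probabilities (rows summing to 1), which the PWM
    builder recognises and rescales by its documented convention.
    """
    if dialect not in ("jaspar_pfm", "meme_minimal"):
        raise ValueError(f"unknown motif dialect {dialect!r}")
    fmt = "jaspar" if dialect == "jaspar_pfm" else "minimal"
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
        entries = []
        for m in parsed:
            motif_id = getattr(m, "matrix_id", None) or m.name
            mat = _matrix_from_bio(m)
            if dialect == "meme_minimal":
                # Biopython rescales the letter-probability matrix by nsites;
                # restore the probabilities as printed in the file.
                mat = mat / mat.sum(axis=1, keepdims=True)
            entries.append(MotifEntry(motif_id=motif_id, matrix=mat))
    lib = MotifLibrary(entries)
    logger.info("read_motifs: %d motifs (%s) from %s", len(lib), dialect, path)
    return lib


def write_motifs(library: MotifLibrary, path, dialect: str = "jaspar_pfm") -> None:
    if dialect == "jaspar_pfm":
        with open(path, "w") as fh:
            for e in library:
                fh.write(f">{e.motif_id} {e.motif_id}\n")
                for bi, base in enumerate("ACGT"):
                    vals = " ".join(_fmt_num(v) for v in e.matrix[:, bi])
                    fh.write(f"{base} [ {vals} ]\n")
    elif dialect == "meme_minimal":
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            for e in library:
                probs = e.matrix / e.matrix.sum(axis=1, keepdims=True)
                fh.write(f"MOTIF {e.motif_id}\n")
                fh.write(
                    f"letter-probability matrix: alength= 4 w= {len(probs)} nsites= 100 E= 0\n"
                )
                for row in probs:
                    fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
                fh.write("\n")
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6f}"


def read_family_map(path) -> FamilyMap:
    """Two-column TSV motif_id -> family (header optional)."""
    fm = FamilyMap()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "motif_id":
                continue
            if len(parts) < 2:
                raise ValueError(f"family map line with < 2 columns: {line!r}")
            fm[parts[0]] = parts[1]
    return fm


def write_family_map(fm: FamilyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tfamily\n")
        for motif_id in sorted(fm):
            fh.write(f"{motif_id}\t{fm[motif_id]}\n")


# ---------------------------------------------------------------------------
# Hit tables


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "motif_id": h.motif_id,
            "family": h.family,
            "sequence_name": h.sequence_name,
            "start": h.start,
            "stop": h.stop,
            "strand": h.strand,
            "score": h.score,
            "p_value": h.p_value,
            "matched_sequence": h.matched_sequence,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(
        ["sequence_name", "start", "motif_id", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    """Hit table, 1-based inclusive forward-strand coordinates, deterministic order."""
    df = hits_to_frame(hits)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    logger.info("write_hits_tsv: %d hits -> %s", len(df), path)


def read_hits_tsv(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "matched_sequence": str})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            MotifHit(
                motif_id=str(row.motif_id),
                family="" if pd.isna(row.family) else str(row.family),
                sequence_name=str(row.sequence_name),
                start=int(row.start),
                stop=int(row.stop),
                strand=str(row.strand),
                score=float(row.score),
                p_value=float(row.p_value),
                matched_sequence=str(row.matched_sequence),
            )
        )
    return hits
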