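"""Core-promoter element annotation: Y-patch, TATA variants, MTE/BREu/DCE-S-I.

The Y-patch is a pyrimidine (C/T)-rich plant core-promoter element that can
substitute for a TATA-box.  Detection here is orientation-constrained: only
hits in the gene's own orientation count, at p < 0.0004 when a PWM model is
used.  Because the published Y-patch weight matrix is not freely
redistributable, two models are provided:

* a pluggable PWM slot (supply your own matrix through the motif library);
* :func:`default_y_patch_pwm`, a synthetic pyrimidine-patch PWM (12
  positions, C/T at 0.45 each) whose p < 0.0004 hit set is exactly the
  all-pyrimidine 12-mers under a uniform background; and
* a rule fallback (``model="rule"``): windows of length >= 8 with
  pyrimidine fraction >= 0.8 and at least one C, merged over overlaps.

Core sequences passed to these functions must already be in gene
orientation (the strand-aware extraction lives in
:mod:`crmscreen.geometry`); positions in the returned hits are 1-based
within that core sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .pwm import MotifHit, PositionWeightMatrix, build_pwm, scan_sequence

logger = logging.getLogger("crmscreen")

__all__ = [
    "CorePromoterAnnotation",
    "default_y_patch_pwm",
    "detect_y_patch",
    "detect_tata_variant",
    "detect_core_elements",
    "count_y_patches",
]

Y_PATCH_P_THRESHOLD = 4e-4
Y_PATCH_RULE_MIN_LEN = 8
Y_PATCH_RULE_MIN_PY_FRAC = 0.8
TATA_HEXAMERS_DEFAULT = ("TATAAA", "ATTAAA")
CORE_ELEMENT_FAMILIES = ("MTE", "BREu", "DCE_S_I")

_PYRIMIDINES = frozenset("CT")


@dataclass
class CorePromoterAnnotation:
    """Per-gene core-promoter annotation (all hits in gene orientation)."""

    gene_id: str
    y_patch_hits: list[MotifHit] = field(default_factory=list)
    tata_hits: list[MotifHit] = field(default_factory=list)
    other_elements: dict[str, list[MotifHit]] = field(default_factory=dict)

    @property
    def y_patch_count(self) -> int:
        return count_y_patches(self.y_patch_hits)

    @property
    def has_y_patch(self) -> bool:
        return bool(self.y_patch_hits)


def default_y_patch_pwm(length: int = 12) -> PositionWeightMatrix:
    """Synthetic pyrimidine-patch PWM standing in for the unpublished model.

    Every position favours C and T equally (0.45 each after pseudocount);
    under a uniform background the p < 0.0004 threshold admits exactly the
    all-pyrimidine words (mass 0.5^length ~= 2.4e-4 at the default length).
    """
    counts = np.tile(np.array([5.0, 45.0, 5.0, 45.0]), (length, 1))
    return build_pwm(counts, motif_id="Ypatch_synthetic")


def _rule_y_patch(core_sequence: str, sequence_name: str) -> list[MotifHit]:
    """Pyrimidine-run rule: length >= 8 windows, py fraction >= 0.8, >= 1 C; merged."""
    seq = core_sequence.upper()
    L = Y_PATCH_RULE_MIN_LEN
    need = math.ceil(Y_PATCH_RULE_MIN_PY_FRAC * L - 1e-9)
    qualifying: list[tuple[int, int]] = []  # 0-based [start, end) of length-L windows
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if sum(c in _PYRIMIDINES for c in window) >= need and "C" in window:
            qualifying.append((i, i + L))
    merged: list[tuple[int, int]] = []
    for s, e in qualifying:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    hits = []
    for s, e in merged:
        window = seq[s:e]
        hits.append(
            MotifHit(
                motif_id="Ypatch_rule",
                family="Ypatch",
                sequence_name=sequence_name,
                start=s + 1,
                stop=e,
                strand="+",
                score=float(sum(c in _PYRIMIDINES for c in window)),
                p_value=Y_PATCH_P_THRESHOLD,  # upper bound only; rule hits carry no exact p
                matched_sequence=window,
            )
        )
    return hits


def detect_y_patch(
    core_sequence: str,
    y_patch_model: PositionWeightMatrix | str | None = None,
    p_threshold: float = Y_PATCH_P_THRESHOLD,
    sequence_name: str = "core",
) -> list[MotifHit]:
    """Orientation-constrained Y-patch hits in a gene-orientation core sequence.

    With a PWM model only the forward strand is scanned and hits must have
    p strictly below ``p_threshold``.  ``model="rule"`` uses the pyrimidine-
    run fallback; ``None`` uses the built-in synthetic PWM.
    """
    if y_patch_model is None:
        y_patch_model = default_y_patch_pwm()
    if isinstance(y_patch_model, str):
        if y_patch_model != "rule":
            raise ValueError(f"unknown Y-patch model {y_patch_model!r}")
        return _rule_y_patch(core_sequence, sequence_name)
    hits = scan_sequence(
        core_sequence,
        y_patch_model,
        p_threshold=p_threshold,
        strands="forward",
        sequence_name=sequence_name,
        family="Ypatch",
    )
    return [h for h in hits if h.p_value < p_threshold]


def detect_tata_variant(
    core_sequence: str,
    hexamers: tuple[str, ...] = TATA_HEXAMERS_DEFAULT,
    tata_pwm: PositionWeightMatrix | None = None,
    p_threshold: float = 1e-3,
    sequence_name: str = "core",
) -> list[MotifHit]:
    """Exact-match TATA hexamer hits (gene orientation), plus PWM hits if supplied.

    Positions are 1-based within the core sequence and refer to the 5' base
    of the matched hexamer.
    """
    seq = core_sequence.upper()
    hits: list[MotifHit] = []
    for hexamer in hexamers:
        h = hexamer.upper()
        i = seq.find(h)
        while i != -1:
            hits.append(
                MotifHit(
                    motif_id=f"TATA_{h}",
                    family="TATA",
                    sequence_name=sequence_name,
                    start=i + 1,
                    stop=i + len(h),
                    strand="+",
                    score=float(len(h)),
                    p_value=0.25 ** len(h),  # exact-word background probability
                    matched_sequence=h,
                )
            )
            i = seq.find(h, i + 1)
    if tata_pwm is not None:
        hits.extend(
            scan_sequence(
                seq,
                tata_pwm,
                p_threshold=p_threshold,
                strands="forward",
                sequence_name=sequence_name,
                family="TATA",
            )
        )
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def detect_core_elements(
    core_sequence: str,
    polII_library,
    family_map,
    p_threshold: float = 1e-3,
    families: tuple[str, ...] = CORE_ELEMENT_FAMILIES,
    sequence_name: str = "core",
) -> dict[str, list[MotifHit]]:
    """Per-family PWM hits (gene orientation) for POLII core-promoter elements."""
    from .pwm import build_pwm as _build

    out: dict[str, list[MotifHit]] = {fam: [] for fam in families}
    seen: set[str] = set()
    for entry in polII_library:
        fam = entry.family or family_map.family_of(entry.motif_id)
        if fam not in out:
            continue
        seen.add(fam)
        pwm = _build(entry.matrix, motif_id=entry.motif_id)
        out[fam].extend(
            scan_sequence(
                core_sequence,
                pwm,
                p_threshold=p_threshold,
                strands="forward",
                sequence_name=sequence_name,
                family=fam,
            )
        )
    for fam in families:
        if fam not in seen:
            logger.warning("core element family %s absent from library; empty hit list", fam)
    return out


def count_y_patches(hits: list[MotifHit]) -> int:
    """Non-overlapping Y-patch count by greedy leftmost collapse of overlaps."""
    count = 0
    last_stop = 0
    for h in sorted(hits, key=lambda h: (h.start, h.stop)):
        if h.start > last_stop:
            count += 1
            last_stop = h.stop
    return count


def annotate_core_promoter(
    gene_id: str,
    core_sequence: str,
    y_patch_model=None,
    polII_library=None,
    family_map=None,
    tata_hexamers: tuple[str, ...] = TATA_HEXAMERS_DEFAULT,
    y_patch_p: float = Y_PATCH_P_THRESHOLD,
) -> CorePromoterAnnotation:
    """Full annotation of one gene-orientation core-promoter sequence."""
    ann = CorePromoterAnnotation(gene_id=gene_id)
    ann.y_patch_hits = detect_y_patch(
        core_sequence, y_patch_model, p_threshold=y_patch_p, sequence_name=gene_id
    )
    ann.tata_hits = detect_tata_variant(core_sequence, tata_hexamers, sequence_name=gene_id)
    if polII_library is not None and family_map is not None:
        ann.other_elements = detect_core_elements(
            core_sequence, polII_library, family_map, sequence_name=gene_id
        )
    return ann
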