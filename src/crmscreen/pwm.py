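"""Position weight matrices, log-odds scoring, and exact occurrence p-values.

The scoring model is the classical one used by motif occurrence scanners:
a motif of length ``L`` is a matrix of per-position base probabilities; a
window of sequence is scored as the sum over positions of
``log2(prob[i, base] / background[base])`` (bits).  The p-value of a score
is the probability that a random window drawn i.i.d. from the background
scores at least as high.  It is computed exactly for a discretised version
of the score (position-wise convolution of the per-position score
distributions), so no asymptotic approximation is involved; discretisation
error in the score is bounded by ``L * granularity / 2`` bits.

Both scanning and the null distribution use the same integer score tables,
so a reported p-value is the exact tail mass of the discretised score at
the window's own bin (the bin containing the score is always included, so
p is never understated relative to the discretised model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1e-3  # bits per bin
PROBABILITY_SCALE = 100.0  # probability matrices are rescaled to this many pseudo-counts

__all__ = [
    "PositionWeightMatrix",
    "ScoreDistribution",
    "MotifHit",
    "build_pwm",
    "score_window",
    "score_distribution",
    "scan_sequence",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A motif scoring object: base probabilities plus log-odds in bits."""

    motif_id: str
    probs: np.ndarray  # L x 4, rows sum to 1, all > 0
    background: np.ndarray  # length 4, sums to 1, all > 0
    log_odds: np.ndarray  # L x 4, bits

    def __post_init__(self):
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError(f"{self.motif_id}: log-odds not finite")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        """PWM scoring the reverse-complement strand (rows flipped, A<->T, C<->G)."""
        return PositionWeightMatrix(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            log_odds=self.log_odds[::-1, ::-1].copy(),
        )

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence.

    ``start``/``stop`` are 1-based inclusive positions on the forward strand
    of the scanned sequence regardless of hit strand; ``matched_sequence``
    is the motif-orientation window (reverse-complemented for '-' hits).
    """

    motif_id: str
    family: str
    sequence_name: str
    start: int
    stop: int
    strand: str
    score: float
    p_value: float
    matched_sequence: str

    def __post_init__(self):
        if not (1 <= self.start <= self.stop):
            raise ValueError(f"bad hit interval {self.start}..{self.stop}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


def _normalise_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive values")
    return bg / bg.sum()


def build_pwm(
    counts_or_probs,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background=None,
    motif_id: str = "motif",
) -> PositionWeightMatrix:
    """Build a PWM from a count or probability matrix.

    Counts: ``probs[i, b] = (count[i, b] + pseudocount * bg[b]) / (rowsum + pseudocount)``.
    A matrix whose rows all sum to 1 (within 1e-3) is treated as probabilities
    and rescaled to pseudo-counts of 100 before the pseudocount is applied;
    a matrix where only some rows look like probabilities is rejected.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mat = np.asarray(counts_or_probs, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError(f"{motif_id}: matrix must be L x 4, got {mat.shape}")
    if mat.shape[0] < 1:
        raise ValueError(f"{motif_id}: empty matrix")
    if np.any(mat < 0):
        raise ValueError(f"{motif_id}: negative entries")
    rowsums = mat.sum(axis=1)
    if np.any(rowsums == 0):
        raise ValueError(f"{motif_id}: all-zero row")
    prob_like = np.abs(rowsums - 1.0) <= 1e-3
    if prob_like.all():
        mat = mat / rowsums[:, None] * PROBABILITY_SCALE
    elif prob_like.any():
        raise ValueError(f"{motif_id}: mixed count and probability rows")
    bg = _normalise_background(background)
    rowsums = mat.sum(axis=1)
    probs = (mat + pseudocount * bg[None, :]) / (rowsums + pseudocount)[:, None]
    log_odds = np.log2(probs / bg[None, :])
    return PositionWeightMatrix(motif_id=motif_id, probs=probs, background=bg, log_odds=log_odds)


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Exact log-odds score (bits) of a single window; rejects N and length mismatch."""
    w = window.upper()
    if len(w) != pwm.length:
        raise ValueError(f"window length {len(w)} != motif length {pwm.length}")
    total = 0.0
    for i, base in enumerate(w):
        j = BASE_INDEX.get(base)
        if j is None:
            raise ValueError(f"unscorable base {base!r} at window offset {i}")
        total += pwm.log_odds[i, j]
    return float(total)


class ScoreDistribution:
    """Exact null distribution of the discretised total score under the background.

    Per-position log-odds are rounded to integer multiples of ``granularity``;
    the distribution of their sum over a random background window is obtained
    by convolving the (at most four-point) per-position distributions.  The
    survival function ``P(S >= s)`` is exact for the discretised score.
    """

    def __init__(self, pwm: PositionWeightMatrix, granularity: float = DEFAULT_GRANULARITY):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = float(granularity)
        self.int_scores = np.rint(pwm.log_odds / granularity).astype(np.int64)  # L x 4
        bg = pwm.background
        pmf = np.array([1.0])
        offset = 0  # integer score of pmf[0]
        for i in range(pwm.length):
            row = self.int_scores[i]
            lo, hi = int(row.min()), int(row.max())
            new = np.zeros(len(pmf) + (hi - lo), dtype=float)
            for b in range(4):
                shift = int(row[b]) - lo
                new[shift : shift + len(pmf)] += pmf * bg[b]
            pmf = new
            offset += lo
        self.min_int = offset
        self.pmf = pmf
        self.min_score_bits = pwm.min_score()
        self.max_score_bits = pwm.max_score()
        # survival over integer scores, monotone non-increasing by construction
        sf = np.cumsum(pmf[::-1])[::-1]
        self.sf = np.minimum(sf, 1.0)

    @property
    def max_int(self) -> int:
        return self.min_int + len(self.pmf) - 1

    def pvalue_int(self, int_score: int) -> float:
        """P(S >= int_score) for the discretised score; clamped to (0, 1]."""
        idx = int_score - self.min_int
        if idx <= 0:
            return 1.0
        if idx >= len(self.sf):
            return 0.0  # above the attainable maximum; no real window reaches here
        return float(max(self.sf[idx], np.nextafter(0, 1)))

    def pvalue(self, score_bits: float) -> float:
        """P-value of a float score, taken at the bin containing the score.

        The score is floored onto the bin grid, so p is never understated;
        scores at or below the attainable minimum return 1, scores above the
        attainable maximum return 0.
        """
        if score_bits <= self.min_score_bits + 1e-12:
            return 1.0
        if score_bits > self.max_score_bits + 1e-12:
            return 0.0
        return self.pvalue_int(int(math.floor(score_bits / self.granularity + 1e-9)))

    def pvalues_int(self, int_scores: np.ndarray) -> np.ndarray:
        idx = np.clip(int_scores - self.min_int, 0, len(self.sf) - 1)
        p = self.sf[idx]
        p = np.where(int_scores - self.min_int <= 0, 1.0, p)
        return np.maximum(p, np.nextafter(0, 1))


def score_distribution(
    pwm: PositionWeightMatrix, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact discretised null score distribution for ``pwm`` (cached on the PWM)."""
    cache = getattr(pwm, "_dist_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(pwm, "_dist_cache", cache)
    key = float(granularity)
    if key not in cache:
        cache[key] = ScoreDistribution(pwm, granularity)
    return cache[key]


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N and friends) -> -1."""
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_int_scores(codes: np.ndarray, int_table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of every window plus a validity mask (no N in window)."""
    L = int_table.shape[0]
    n = len(codes) - L + 1
    totals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for j in range(L):
        col = codes[j : j + n]
        valid &= col >= 0
        totals += int_table[j, safe[j : j + n]]
    return totals, valid


def scan_sequence(
    sequence: str,
    pwm: PositionWeightMatrix,
    p_threshold: float = 1e-3,
    strands: str = "both",
    granularity: float = DEFAULT_GRANULARITY,
    sequence_name: str = "seq",
    family: str = "",
) -> list[MotifHit]:
    """Report every window with occurrence p-value <= ``p_threshold``.

    Both strands are scanned by default; minus-strand hits are reported in
    forward-strand coordinates with ``matched_sequence`` reverse-complemented.
    Windows containing non-ACGT characters are skipped.  The p-value for a
    minus-strand window is computed from the same null distribution (the
    reverse-complement scoring function has the identical score multiset
    under a strand-symmetric background, uniform by default).
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    seq = sequence.upper()
    L = pwm.length
    if len(seq) < L:
        return []
    dist = score_distribution(pwm, granularity)
    codes = encode(seq)
    hits: list[MotifHit] = []

    tables = {"+": dist.int_scores}
    if strands == "both":
        # score of revcomp(window) under pwm == score of window under rc table
        tables["-"] = dist.int_scores[::-1, ::-1]

    for strand, table in tables.items():
        totals, valid = _window_int_scores(codes, table)
        pvals = dist.pvalues_int(totals)
        take = valid & (pvals <= p_threshold)
        for i in np.flatnonzero(take):
            window = seq[i : i + L]
            matched = window if strand == "+" else reverse_complement(window)
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    family=family,
                    sequence_name=sequence_name,
                    start=int(i) + 1,
                    stop=int(i) + L,
                    strand=strand,
                    score=score_window(pwm, matched),
                    p_value=float(pvals[i]),
                    matched_sequence=matched,
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
    return hits
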