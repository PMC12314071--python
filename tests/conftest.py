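"""Shared fixtures: small PWMs, exhaustive-enumeration oracles, simulated data."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crmscreen.pwm import MotifHit, PositionWeightMatrix, build_pwm


def sharp_counts(consensus: str, hit: float = 97.0, miss: float = 1.0) -> np.ndarray:
    mat = np.full((len(consensus), 4), miss)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = hit
    return mat


def enumerate_null(pwm: PositionWeightMatrix):
    """Independent oracle: exact scores and background mass of all 4^L words.

    Returns (words, scores, pvalue_fn) where pvalue_fn(s) is the exact
    background probability of a word scoring >= s.
    """
    L = pwm.length
    idx = np.array(list(itertools.product(range(4), repeat=L)))
    scores = pwm.log_odds[np.arange(L)[None, :], idx].sum(axis=1)
    mass = pwm.background[idx].prod(axis=1)
    order = np.argsort(-scores)
    sorted_scores = scores[order]
    tail_mass = np.cumsum(mass[order])

    def pvalue(s: float) -> float:
        k = np.searchsorted(-sorted_scores, -s, side="right")
        return float(tail_mass[k - 1]) if k > 0 else 0.0

    words = ["".join("ACGT"[i] for i in w) for w in idx]
    return words, scores, pvalue


def make_hit(
    family: str,
    start: int,
    length: int = 9,
    p_value: float = 1e-6,
    motif_id: str | None = None,
    strand: str = "+",
    sequence_name: str = "chr1",
) -> MotifHit:
    return MotifHit(
        motif_id=motif_id or f"{family}_syn1",
        family=family,
        sequence_name=sequence_name,
        start=start,
        stop=start + length - 1,
        strand=strand,
        score=10.0,
        p_value=p_value,
        matched_sequence="A" * length,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sharp_pwm():
    return build_pwm(sharp_counts("TTTGACTTT"), motif_id="WRKY_syn1")


@pytest.fixture(scope="session")
def sim_genome_small():
    from crmscreen.simulate import SimulationConfig, simulate_genome

    return simulate_genome(SimulationConfig(seed=11, n_genes=24))
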