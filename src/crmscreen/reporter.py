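"""Reporter-assay quantification: MUG kinetics, LUC/GUS ratios, group statistics.

The fluorometric MUG assay measures GUS enzyme activity as the rate of
4-methylumbelliferone (4-MU) production: fluorescence is read every 2 min
for 20 cycles, the slope of each duplicate reaction is fitted by ordinary
least squares over all cycles, converted to 4-MU amount through a standard
curve fitted on the same plate, averaged across duplicates, and divided by
the protein amount in the reaction (nmol 4-MU/min/mg protein).
Transactivation assays report LUC luminescence divided by the GUS rate per
second, optionally log2-transformed for group tests.

Group comparisons are all-pairwise two-sided tests (Wilcoxon rank-sum for
stable-line MUG data, t-test for transient LUC/GUS data), corrected by
Benjamini-Hochberg over the pairwise family, summarised by a compact letter
display: two groups share a letter iff their adjusted p >= alpha.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crmscreen")

__all__ = [
    "KineticSeries",
    "StandardCurve",
    "ActivityMeasurement",
    "ComparisonResult",
    "fit_standard_curve",
    "gus_rate",
    "luc_gus_ratio",
    "compare_constructs",
    "compact_letter_display",
    "fold_change",
]

EXACT_WILCOXON_MAX_N = 20  # combined n at or below which the exact null is used


@dataclass
class KineticSeries:
    """One duplicate reaction's plate-reader time course."""

    line_id: str
    construct_id: str
    duplicate_id: str
    times_min: np.ndarray
    fluorescence: np.ndarray
    protein_mg: float

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.times_min) != len(self.fluorescence):
            raise ValueError(f"{self.line_id}/{self.duplicate_id}: length mismatch")
        if len(self.times_min) < 3:
            raise ValueError(f"{self.line_id}/{self.duplicate_id}: need >= 3 readings")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError(f"{self.line_id}/{self.duplicate_id}: times not strictly increasing")


@dataclass
class StandardCurve:
    """OLS fit fluorescence = slope * concentration + intercept."""

    slope: float  # AU per nmol 4-MU
    intercept: float
    r_squared: float
    points: pd.DataFrame

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard curve slope must be positive")


@dataclass
class ActivityMeasurement:
    line_id: str
    construct_id: str
    rate: float  # nmol 4-MU/min/mg protein
    duplicate_slopes: tuple[float, ...] = ()

    def __post_init__(self):
        if not np.isfinite(self.rate):
            raise ValueError(f"{self.line_id}: non-finite rate")


def fit_standard_curve(points: pd.DataFrame) -> StandardCurve:
    """Fit the 4-MU standard curve by ordinary least squares.

    ``points`` needs columns ``conc`` (nmol 4-MU) and ``fluorescence`` (AU),
    with at least two distinct concentrations.
    """
    conc = np.asarray(points["conc"], dtype=float)
    fluo = np.asarray(points["fluorescence"], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("standard curve needs >= 2 distinct concentrations")
    fit = stats.linregress(conc, fluo)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=points.reset_index(drop=True),
    )


def gus_rate(duplicates: list[KineticSeries], curve: StandardCurve) -> ActivityMeasurement:
    """GUS rate of one line: per-duplicate OLS slope, curve conversion, average.

    slope (AU/min) / curve slope (AU/nmol) -> nmol/min, averaged across the
    duplicate reactions and divided by mg protein in the reaction.
    """
    if not duplicates:
        raise ValueError("no kinetic series supplied")
    line_ids = {d.line_id for d in duplicates}
    if len(line_ids) != 1:
        raise ValueError(f"duplicates from different lines: {sorted(line_ids)}")
    protein = duplicates[0].protein_mg
    if protein <= 0:
        raise ValueError(f"{duplicates[0].line_id}: protein amount must be positive")
    slopes = []
    for d in duplicates:
        fit = stats.linregress(d.times_min, d.fluorescence)
        slopes.append(float(fit.slope))
    mean_slope_au = float(np.mean(slopes))
    rate = mean_slope_au / curve.slope / protein
    return ActivityMeasurement(
        line_id=duplicates[0].line_id,
        construct_id=duplicates[0].construct_id,
        rate=rate,
        duplicate_slopes=tuple(slopes),
    )


def luc_gus_ratio(luc_luminescence: float, gus_rate_per_second: float, log2: bool = False) -> float:
    """Transcriptional activity: LUC luminescence / GUS rate per second."""
    if gus_rate_per_second <= 0:
        raise ValueError("GUS rate must be positive to normalise LUC")
    ratio = luc_luminescence / gus_rate_per_second
    return float(np.log2(ratio)) if log2 else float(ratio)


@dataclass
class ComparisonResult:
    pairs: pd.DataFrame  # group1, group2, statistic, p_value, p_adjusted
    letters: dict[str, str]
    alpha: float
    excluded: list[str] = field(default_factory=list)


def _pair_test(x: np.ndarray, y: np.ndarray, test: str) -> tuple[float, float]:
    if test == "wilcoxon":
        method = "exact" if (len(x) + len(y) <= EXACT_WILCOXON_MAX_N and not _has_ties(x, y)) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        res = stats.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def _has_ties(x, y) -> bool:
    combined = np.concatenate([x, y])
    return len(np.unique(combined)) < len(combined)


def compare_constructs(
    groups: dict[str, np.ndarray],
    test: str = "wilcoxon",
    alpha: float = 0.05,
) -> ComparisonResult:
    """All pairwise two-sided tests with Benjamini-Hochberg correction.

    ``groups`` maps construct id to its per-line measurements.  Groups of
    size < 2 are excluded with a warning.  The compact letter display
    assigns letters so that two groups share a letter iff their adjusted
    p >= ``alpha``.
    """
    usable = {}
    excluded = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            logger.warning("group %s has %d value(s); excluded from comparison", name, len(vals))
            excluded.append(name)
        else:
            usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need >= 2 groups of size >= 2")
    names = list(usable)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        statistic, p = _pair_test(usable[g1], usable[g2], test)
        rows.append({"group1": g1, "group2": g2, "statistic": statistic, "p_value": p})
    pairs = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(pairs["p_value"], method="fdr_bh")
    pairs["p_adjusted"] = p_adj
    significant = {
        frozenset((r.group1, r.group2)) for r in pairs.itertuples() if r.p_adjusted < alpha
    }
    letters = compact_letter_display(names, significant)
    return ComparisonResult(pairs=pairs, letters=letters, alpha=alpha, excluded=excluded)


def compact_letter_display(groups: list[str], significant_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant_pairs`` holds the pairs that must NOT share a letter; the
    result assigns each group a string of letters such that two groups share
    at least one letter iff their pair is not significant.  Letter order
    follows group input order (deterministic).
    """
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant_pairs, key=lambda p: sorted(p)):
        g1, g2 = sorted(pair)
        new_columns: list[set[str]] = []
        for col in columns:
            if g1 in col and g2 in col:
                new_columns.append(col - {g1})
                new_columns.append(col - {g2})
            else:
                new_columns.append(col)
        # absorb: drop empties, duplicates, and proper subsets of other columns
        uniq: list[set[str]] = []
        for col in new_columns:
            if col and col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        symbol = alphabet[i % 26] * (i // 26 + 1)
        for g in groups:
            if g in col:
                letters[g] += symbol
    return letters


def fold_change(groups: dict[str, np.ndarray], reference: str) -> dict[str, float]:
    """Median fold change of each construct relative to a reference construct."""
    if reference not in groups:
        raise KeyError(f"reference construct {reference!r} not among groups")
    ref = float(np.median(np.asarray(groups[reference], dtype=float)))
    if ref <= 0:
        raise ValueError("reference median must be positive")
    return {name: float(np.median(np.asarray(vals, dtype=float)) / ref) for name, vals in groups.items()}
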