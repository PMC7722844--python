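"""Genetics of the expression screen.

Phenotype calls (inclusive >= 30% boundary), recombination-frequency
estimation on a phenotype-selected population, linkage calls (strict < 20%),
YET complementation scoring (strict < 30%) and per-construct summary rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic_data import ALLELE_MISSING, ALLELE_MUTANT, ALLELE_POLYMORPHIC

PHENOTYPE_THRESHOLD = 0.30   # inclusive: "at least 30%"
COMPLEMENTATION_THRESHOLD = 30.0  # strict: complemented if YET < 30%
LINKAGE_THRESHOLD = 20.0     # strict: linked if RF < 20%

YET_CLASSES = ("0", "1-10", "11-20", "21-29", ">=30")


def round1(x: float) -> float:
    """Round half away from zero to one decimal (reporting only)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class TransformantScreen:
    line_id: str
    n_yfp_expressing: int
    n_total: int

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 <= self.n_yfp_expressing <= self.n_total):
            raise ValueError("n_yfp_expressing must be in [0, n_total]")


@dataclass(frozen=True)
class YetClass:
    yet_percent: float      # rounded to 1 decimal for reporting
    yet_class: str          # one of YET_CLASSES
    complemented: bool      # exact percent < 30


def score_expression_phenotype(
    n_yfp: int, n_total: int, threshold: float = PHENOTYPE_THRESHOLD
) -> bool:
    """True iff n_yfp / n_total >= threshold (inclusive boundary)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_yfp / n_total >= threshold


def yet_score(screen: TransformantScreen) -> YetClass:
    """YET percentage, its printed class bin, and the complementation flag.

    Class bins partition the exact percentage as [0], (0,10], (10,20],
    (20,30), [30,inf); complemented iff the exact percentage is < 30, so the
    flag always agrees with the class partition.
    """
    exact = 100.0 * screen.n_yfp_expressing / screen.n_total
    if exact == 0:
        cls = "0"
    elif exact <= 10:
        cls = "1-10"
    elif exact <= 20:
        cls = "11-20"
    elif exact < 30:
        cls = "21-29"
    else:
        cls = ">=30"
    return YetClass(round1(exact), cls, exact < COMPLEMENTATION_THRESHOLD)


def summarize_complementation(screens: Sequence[TransformantScreen]) -> dict:
    """Table-1-style row for one construct/strain combination.

    Percentages of lines per complementation class (1 decimal) plus the total
    complementation efficiency (YET < 30%); the total count equals the sum of
    the four complementation-class counts exactly.
    """
    if not screens:
        raise ValueError("need at least one line")
    counts = {cls: 0 for cls in YET_CLASSES}
    for screen in screens:
        counts[yet_score(screen).yet_class] += 1
    n = len(screens)
    complemented = sum(counts[c] for c in YET_CLASSES[:4])
    row = {"n_lines": n, "total_lt30": round1(100.0 * complemented / n)}
    for cls in YET_CLASSES:
        row[f"class_{cls}"] = round1(100.0 * counts[cls] / n)
        row[f"count_{cls}"] = counts[cls]
    row["count_lt30"] = complemented
    return row


def min_clones_analyzed(n_segregants: int, avg_transformants_per_segregant: int) -> int:
    """Lower bound on clones screened: segregants x average transformants."""
    if n_segregants < 0 or avg_transformants_per_segregant < 0:
        raise ValueError("counts must be non-negative")
    return n_segregants * avg_transformants_per_segregant


# ---------------------------------------------------------------------------
# recombination frequency on a selected population
# ---------------------------------------------------------------------------


def recombination_frequency(alleles: Iterable[str]) -> dict:
    """RF% for one marker over phenotype-selected segregants.

    Every selected segregant carries the causal allele, so a marker allele
    from the polymorphic parent is a recombinant.  Missing genotypes are
    excluded from the denominator.  Returns rf_percent (1 decimal),
    n_recombinant and n_scored.
    """
    n_rec = n_scored = 0
    for allele in alleles:
        if allele == ALLELE_MISSING:
            continue
        if allele not in (ALLELE_MUTANT, ALLELE_POLYMORPHIC):
            raise ValueError(f"unknown allele origin {allele!r}")
        n_scored += 1
        if allele == ALLELE_POLYMORPHIC:
            n_rec += 1
    if n_scored == 0:
        raise ValueError("zero scored segregants")
    return {
        "rf_percent": round1(100.0 * n_rec / n_scored),
        "n_recombinant": n_rec,
        "n_scored": n_scored,
    }


def call_linkage(rf_percent: float, threshold: float = LINKAGE_THRESHOLD) -> bool:
    """Linked iff RF < threshold (strict boundary)."""
    if not (0 <= rf_percent <= 100):
        raise ValueError("rf_percent must be in [0, 100]")
    return rf_percent < threshold


def rf_table(genotypes: pd.DataFrame, markers: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-marker RF summary from a segregant x marker genotype table."""
    if markers is None:
        markers = [c for c in genotypes.columns if c != "phenotype"]
    rows = []
    for marker in markers:
        rec = recombination_frequency(genotypes[marker])
        rec["marker"] = marker
        rec["linked"] = call_linkage(rec["rf_percent"])
        rows.append(rec)
    return pd.DataFrame(rows)[["marker", "rf_percent", "n_recombinant", "n_scored", "linked"]]
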