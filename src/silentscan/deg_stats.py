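"""Count-matrix differential-expression stage.

FPKM computation, median-of-ratios library-size normalization, a Welch-test
per-gene stand-in for the original inference tooling, Benjamini-Hochberg
adjustment, the two DEG criteria (strict thresholds), and the four-way
directional Venn intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEGCriteria:
    """Thresholds are strict inequalities exactly as configured.

    ``ma`` mode: |log2FC| > lfc_threshold and padj < padj_threshold.
    ``venn`` mode adds mean FPKM > fpkm_threshold.
    """

    mode: str = "ma"               # "ma" or "venn"
    lfc_threshold: float = 1.0     # fold change > 2 <=> |log2FC| > 1
    padj_threshold: float = 0.01
    fpkm_threshold: float = 1.0

    def __post_init__(self):
        if self.mode not in ("ma", "venn"):
            raise ValueError("mode must be 'ma' or 'venn'")


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """FPKM = count / (length/1000) / (total/1e6).

    ``totals`` defaults to the per-sample column sums of the count matrix.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


# ---------------------------------------------------------------------------
# normalization and the per-gene test
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios factors against the geometric-mean pseudo-reference.

    Genes with a zero in any sample are excluded from factor estimation;
    if no gene survives, factors fall back to relative library totals.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        totals = counts.sum(axis=0).astype(float)
        factors = totals.to_numpy()
    else:
        logc = np.log(positive.to_numpy(dtype=float))
        ref = logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logc - ref, axis=0))
    # anchor the median factor at 1 so rescaling a minority of samples does
    # not shift the normalized scale of the others
    factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth's parametrization)."""
    from scipy.special import polygamma

    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10:
            break
    return float(y)


def _moderate_variances(s2: np.ndarray, df: float):
    """Empirical-Bayes prior (d0, s0^2) for per-gene variances.

    Method-of-moments fit on log variances; returns (inf, mean variance)
    when there is no excess spread to shrink against.
    """
    from scipy.special import digamma, polygamma

    usable = s2[s2 > 0]
    if usable.size < 2:
        return np.inf, float(usable.mean()) if usable.size else 1.0
    e = np.log(usable) - digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2 * _trigamma_inverse(evar)
    s0 = float(np.exp(e.mean() + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0


def test_de(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene log2 fold-change (B vs A) and a moderated-t p-value.

    Counts are size-factor normalized; the test is a two-sided t on
    log2(normalized + pseudocount) with the pooled per-gene variance shrunk
    toward an empirical-Bayes prior estimated from all genes, which restores
    power at small replicate numbers.  Genes with zero counts in every sample
    are reported with log2FC 0 and p 1 and marked ``all_zero`` (to be
    excluded from the BH n).  Deterministic.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = counts[list(group_a) + list(group_b)]
    norm = sub / size_factors(sub)
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)

    lfc = np.log2(b.mean(axis=1) + PSEUDOCOUNT) - np.log2(a.mean(axis=1) + PSEUDOCOUNT)

    la = np.log2(a + PSEUDOCOUNT)
    lb = np.log2(b + PSEUDOCOUNT)
    na, nb = la.shape[1], lb.shape[1]
    df_resid = na + nb - 2
    ss = la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df_resid

    all_zero = (sub == 0).all(axis=1).to_numpy()
    d0, s0 = _moderate_variances(s2[~all_zero], df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = 1e6
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    diff = lb.mean(axis=1) - la.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1 / na + 1 / nb))
    pvalues = 2 * stats.t.sf(np.abs(t), min(df_total, 1e6))
    pvalues = np.where(np.isnan(pvalues), np.where(diff == 0, 1.0, 0.0), pvalues)

    lfc[all_zero] = 0.0
    pvalues[all_zero] = 1.0

    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvalues, "all_zero": all_zero}, index=counts.index
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Standard step-up adjustment, order restored, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def gene_stats(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    gene_lengths: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Full per-gene table: log2fc, p, BH-adjusted p, and mean FPKM.

    All-zero genes are excluded from the BH n and get padj 1.
    """
    table = test_de(counts, group_a, group_b)
    padj = np.ones(len(table))
    active = ~table["all_zero"].to_numpy()
    padj[active] = bh_adjust(table.loc[active, "pvalue"].to_numpy())
    table["padj"] = padj
    if gene_lengths is not None:
        table["mean_fpkm"] = fpkm(counts, gene_lengths).mean(axis=1)
    return table


# ---------------------------------------------------------------------------
# DEG calling and the four-way Venn
# ---------------------------------------------------------------------------


def call_degs(table: pd.DataFrame, criteria: DEGCriteria = DEGCriteria()):
    """Return (up, down) gene-id sets under the configured strict filters."""
    if len(table) == 0:
        return set(), set()
    passing = (table["log2fc"].abs() > criteria.lfc_threshold) & (
        table["padj"] < criteria.padj_threshold
    )
    if criteria.mode == "venn":
        if "mean_fpkm" not in table.columns:
            raise ValueError("venn mode needs a mean_fpkm column")
        passing &= table["mean_fpkm"] > criteria.fpkm_threshold
    up = set(table.index[passing & (table["log2fc"] > 0)])
    down = set(table.index[passing & (table["log2fc"] < 0)])
    return up, down


def venn_candidates(set_a: set, set_b: set, set_c: set, set_d: set):
    """Four-way intersection plus all 15 region cardinalities.

    Region keys are strings like ``"AB"`` (in A and B, not in C or D).
    """
    sets = {"A": set_a, "B": set_b, "C": set_c, "D": set_d}
    universe = set_a | set_b | set_c | set_d
    regions = {}
    labels = [
        "".join(combo)
        for size in (1, 2, 3, 4)
        for combo in combinations("ABCD", size)
    ]
    for label in labels:
        inside = set(universe)
        for name, s in sets.items():
            if name in label:
                inside &= s
            else:
                inside -= s
        regions[label] = len(inside)
    return set_a & set_b & set_c & set_d, regions
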