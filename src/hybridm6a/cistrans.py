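"""Cis/trans classification of methylation divergence between alleles.

A hybrid carries both parental alleles in one shared cellular environment.
Differences in methylation that persist between the two alleles of the
hybrid are encoded in the local sequence ("cis"); differences seen between
the parental strains but lost in the hybrid come from the cellular
environment ("trans").  For each site we compute

    delta_parental = log2(score parent A) - log2(score parent B)
    delta_hybrid   = log2(score hybrid allele A) - log2(score hybrid allele B)

on floored enrichment scores (score1), and classify with a fold-change
threshold T (default 1.6 log2 units):

    invariable  |dh| <= T and |dp| <= T
    DM-cis      |dh| >  T and |dp| >  T, same sign
    DM-trans    |dp| >  T and |dh| <= T
    cis-trans   |dh| >  T and (|dp| <= T or opposite sign)

The fraction of divergence attributable to cis is summarized by the Pearson
correlation of delta_hybrid against delta_parental (variance explained =
100 R^2).  Gene-level coupling between methylation (m6A-GI) and expression
(TPM) changes quantifies the downstream consequence of allele-specific
methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("invariable", "DM-cis", "DM-trans", "cis-trans")


@dataclass
class ClassifyParams:
    dm_threshold: float = 1.6
    score_floor: float = 1.0

    def __post_init__(self):
        if self.dm_threshold <= 0:
            raise ValueError("threshold must be > 0")


def delta(score_x: float, score_y: float, floor: float = 1.0) -> float:
    """log2 ratio of two enrichment scores, floored to handle absent sites."""
    if score_x < 0 or score_y < 0:
        raise ValueError("scores must be >= 0")
    return math.log2(max(score_x, floor) / max(score_y, floor))


def classify_site(delta_parental: float, delta_hybrid: float,
                  params: ClassifyParams | None = None) -> str:
    """Assign exactly one evolutionary-mode class from the two deltas."""
    params = params or ClassifyParams()
    t = params.dm_threshold
    dp, dh = delta_parental, delta_hybrid
    if not (np.isfinite(dp) and np.isfinite(dh)):
        raise ValueError("deltas must be finite")
    if abs(dh) <= t and abs(dp) <= t:
        return "invariable"
    if abs(dh) > t and abs(dp) > t and np.sign(dh) == np.sign(dp):
        return "DM-cis"
    if abs(dp) > t and abs(dh) <= t:
        return "DM-trans"
    return "cis-trans"


def compare_sites(
    scores: pd.DataFrame,
    params: ClassifyParams | None = None,
) -> pd.DataFrame:
    """Build the per-site comparison table.

    ``scores`` needs columns score1_parent_a, score1_parent_b,
    score1_hybrid_a, score1_hybrid_b (indexed by site).  Adds
    delta_parental, delta_hybrid and the class label.
    """
    params = params or ClassifyParams()
    df = scores.copy()
    f = params.score_floor
    df["delta_parental"] = [
        delta(x, y, f) for x, y in zip(df["score1_parent_a"], df["score1_parent_b"])
    ]
    df["delta_hybrid"] = [
        delta(x, y, f) for x, y in zip(df["score1_hybrid_a"], df["score1_hybrid_b"])
    ]
    df["site_class"] = [
        classify_site(p, h, params)
        for p, h in zip(df["delta_parental"], df["delta_hybrid"])
    ]
    return df


def cis_fraction(comparisons: pd.DataFrame) -> tuple[float, float]:
    """Pearson R of delta_hybrid vs delta_parental, and variance explained.

    Returns (R, 100 * R^2).  Requires >= 3 sites and nonzero variance on
    both axes.
    """
    dp = np.asarray(comparisons["delta_parental"], dtype=float)
    dh = np.asarray(comparisons["delta_hybrid"], dtype=float)
    if len(dp) < 3:
        raise ValueError("need at least 3 sites")
    if np.var(dp) == 0 or np.var(dh) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(stats.pearsonr(dp, dh).statistic)
    return r, 100.0 * r * r


def methylation_expression_coupling(delta_gi: np.ndarray,
                                    delta_tpm: np.ndarray) -> float:
    """Pearson R between allele-wise log2 fold changes of gene methylation
    (m6A-GI) and of expression (TPM)."""
    delta_gi = np.asarray(delta_gi, dtype=float)
    delta_tpm = np.asarray(delta_tpm, dtype=float)
    if len(delta_gi) != len(delta_tpm) or len(delta_gi) < 3:
        raise ValueError("need >= 3 paired genes")
    return float(stats.pearsonr(delta_gi, delta_tpm).statistic)


def timecourse_coupling(series) -> tuple[list[float], int]:
    """Per-timepoint methylation-expression coupling.

    ``series`` is a sequence of (delta_gi, delta_tpm) pairs, one per
    timepoint.  Returns the R vector and the index of the timepoint with the
    most extreme anticorrelation (minimum R).
    """
    if not len(series):
        raise ValueError("need at least one timepoint")
    rs = [methylation_expression_coupling(gi, tpm) for gi, tpm in series]
    return rs, int(np.argmin(rs))


def compute_tpm(counts, gene_lengths) -> np.ndarray:
    """Transcripts per million from read counts and gene lengths."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("zero total rate")
    return rate / total * 1e6
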