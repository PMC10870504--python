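"""De novo m6A peak calling from IP/input coverage.

The caller reproduces an optimized MeRIP (m6A-seq2) filtering cascade at
near single-nucleotide resolution:

1. ``score2``: mean IP coverage in a 51-nt window around each position,
   divided by the gene's median IP coverage (local enrichment within a gene).
2. Candidate enrichment windows: maximal runs longer than 15 nt with
   score2 > 4 at every position.
3. ``winScore``: window-mean IP score2 over window-mean input score2; a
   window must reach winScore >= 2 in every replicate.
4. Summit: argmax of the aggregate (replicate-summed, library-normalized)
   IP coverage inside the window; the nearest consensus-motif A becomes the
   putative methylated site.
5. ``score1``: mean IP / mean input coverage over an 81-nt window around
   the site; reported sites need score1 > 3.  score1 is the quantity used as
   "m6A enrichment" throughout downstream analyses.
6. Writer-KO filter: sites must lose their enrichment in a methyltransferase
   knockout (window-score ratio WT/KO > 3 in at least one background, plus a
   two-sample Student t-test p < 0.05 on score1 or score2).

Sample- and gene-level indices (m6A-SI, m6A-GI) and the fragment-matched
IDENT-score (enrichment computed only from fragments whose sequence is
identical between alleles) complete the module.

All coverage tracks are per-base numpy arrays over a single gene, 0-based.
Library-size normalization (counts per million within each sample/fraction/
replicate) is expected upstream; score1/score2 are scale-invariant per
track, so normalization only matters when tracks are combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import motif as motif_mod

logger = logging.getLogger(__name__)


@dataclass
class PeakCallParams:
    score2_window: int = 51
    min_window_len: int = 15
    score2_threshold: float = 4.0
    winscore_threshold: float = 2.0
    score1_window: int = 81
    score1_threshold: float = 3.0
    ko_ratio_threshold: float = 3.0
    ko_pvalue_threshold: float = 0.05
    motif: str = "DRAC"
    max_motif_distance: int | None = None
    score1_aggregate: str = "mean"  # or "geometric"

    def __post_init__(self):
        for w in (self.score2_window, self.score1_window):
            if w % 2 == 0:
                raise ValueError("windows must be odd")
        if min(self.score2_threshold, self.winscore_threshold,
               self.score1_threshold, self.ko_ratio_threshold) <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class EnrichmentWindow:
    gene: str
    start: int
    end: int
    winscores: list[float] = field(default_factory=list)
    summit: int | None = None


@dataclass
class M6ASite:
    gene: str
    summit: int
    motif_a_position: int | None
    motif_distance: int | None
    score1: float
    score2_at_summit: float
    window: tuple[int, int]
    ko_pass: bool | None = None
    ko_pvalue: float | None = None


def sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with windows truncated at the edges."""
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return sums / counts


def score2_profile(ip_coverage: np.ndarray, gene_median: float | None = None,
                   window: int = 51) -> np.ndarray | None:
    """Per-position score2 = windowed mean coverage / gene median coverage.

    Returns None (with a warning) for genes whose median coverage is zero.
    """
    ip_coverage = np.asarray(ip_coverage, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if gene_median is None:
        gene_median = float(np.median(ip_coverage))
    if gene_median <= 0:
        logger.warning("gene median coverage is zero; gene skipped")
        return None
    return sliding_mean(ip_coverage, window) / gene_median


def detect_windows(score2: np.ndarray, params: PeakCallParams,
                   gene: str = "") -> list[EnrichmentWindow]:
    """Maximal runs with score2 strictly above threshold at every position
    and run length strictly greater than min_window_len."""
    score2 = np.asarray(score2, dtype=float)
    if not np.all(np.isfinite(score2)):
        raise ValueError("score2 profile must be finite")
    above = score2 > params.score2_threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    out = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start > params.min_window_len:
            out.append(EnrichmentWindow(gene=gene, start=int(start), end=int(end)))
    return out


def winscore_filter(
    windows: list[EnrichmentWindow],
    ip_score2: list[np.ndarray],
    input_score2: list[np.ndarray],
    params: PeakCallParams,
) -> list[EnrichmentWindow]:
    """Keep windows whose winScore (window-mean IP score2 over window-mean
    input score2) reaches the threshold in every replicate.

    A zero input score2 over the window makes the winScore infinite (the
    window is retained and the event logged).
    """
    if len(ip_score2) != len(input_score2):
        raise ValueError("replicate sets must match")
    kept = []
    for win in windows:
        ws = []
        for ip, inp in zip(ip_score2, input_score2):
            num = float(np.mean(ip[win.start:win.end]))
            den = float(np.mean(inp[win.start:win.end]))
            if den == 0:
                logger.warning("input score2 is zero over window %s:%d-%d",
                               win.gene, win.start, win.end)
                ws.append(np.inf)
            else:
                ws.append(num / den)
        if all(w >= params.winscore_threshold for w in ws):
            win.winscores = ws
            kept.append(win)
    return kept


def summit_and_motif(
    window: EnrichmentWindow,
    aggregate_coverage: np.ndarray,
    sequence: str,
    params: PeakCallParams,
) -> tuple[int, int | None, int | None]:
    """Locate the summit and assign the nearest consensus-motif A.

    Summit = argmax of the aggregate coverage within the window (leftmost on
    ties).  Among motif As at equal distance from the summit the upstream one
    is chosen.  Returns (summit, motif_a_position, motif_distance); the motif
    fields are None when no motif lies within max_motif_distance.
    """
    seg = aggregate_coverage[window.start:window.end]
    summit = window.start + int(np.argmax(seg))
    motif_positions = motif_mod.find_motif_positions(sequence, params.motif)
    best = None
    for a in motif_positions:
        d = abs(a - summit)
        if best is None or d < best[1] or (d == best[1] and a < best[0]):
            best = (a, d)
    if best is None:
        return summit, None, None
    if params.max_motif_distance is not None and best[1] > params.max_motif_distance:
        logger.info("no motif within %d nt of summit %d",
                    params.max_motif_distance, summit)
        return summit, None, None
    if best[1] == 0:
        pass
    else:
        # log equidistant ties (upstream already chosen)
        ties = [a for a in motif_positions if abs(a - summit) == best[1]]
        if len(ties) > 1:
            logger.debug("equidistant motifs %s; upstream %d chosen", ties, best[0])
    return summit, best[0], best[1]


def score1(
    ip_coverage: np.ndarray,
    input_coverage: np.ndarray,
    site: int,
    window: int = 81,
) -> float | None:
    """Mean IP over mean input coverage in an odd window centered on the site.

    Both tracks must already be library-size normalized.  None when the input
    mean is zero.
    """
    half = window // 2
    lo, hi = max(0, site - half), min(len(ip_coverage), site + half + 1)
    num = float(np.mean(np.asarray(ip_coverage, dtype=float)[lo:hi]))
    den = float(np.mean(np.asarray(input_coverage, dtype=float)[lo:hi]))
    if den == 0:
        logger.warning("zero input mean around site %d; site dropped", site)
        return None
    return num / den


def aggregate_score1(per_replicate: list[float], how: str = "mean") -> float:
    vals = np.asarray(per_replicate, dtype=float)
    if how == "geometric":
        return float(np.exp(np.mean(np.log(vals))))
    return float(np.mean(vals))


def ko_filter(
    wt_scores1, ko_scores1, wt_scores2, ko_scores2,
    params: PeakCallParams,
    wt_scores1_other=None, ko_scores1_other=None,
) -> tuple[bool, float]:
    """Writer-knockout filter on per-replicate window scores.

    Passes when (mean WT)/(mean KO) window score exceeds the ratio threshold
    in at least one background (the primary one, or the optional second
    species' scores) AND a two-sided equal-variance Student t-test between WT
    and KO replicates is significant for score1 or for score2.  Returns
    (pass, best p-value).
    """
    def _ratio(wt, ko):
        mko = float(np.mean(ko))
        if mko == 0:
            return np.inf
        return float(np.mean(wt)) / mko

    ratios = [_ratio(wt_scores1, ko_scores1)]
    if wt_scores1_other is not None and ko_scores1_other is not None:
        ratios.append(_ratio(wt_scores1_other, ko_scores1_other))
    ratio_ok = any(r > params.ko_ratio_threshold for r in ratios)

    pvals = []
    for wt, ko in ((wt_scores1, ko_scores1), (wt_scores2, ko_scores2)):
        wt = np.asarray(wt, dtype=float)
        ko = np.asarray(ko, dtype=float)
        if len(wt) < 2 or len(ko) < 2:
            continue
        if np.var(wt) == 0 and np.var(ko) == 0:
            pvals.append(0.0 if np.mean(wt) != np.mean(ko) else 1.0)
            continue
        pvals.append(float(stats.ttest_ind(wt, ko, equal_var=True).pvalue))
    pbest = min(pvals) if pvals else 1.0
    return bool(ratio_ok and pbest < params.ko_pvalue_threshold), pbest


def sample_index(
    ip_tracks: dict, input_tracks: dict, sites: list[M6ASite],
    window: int = 81,
) -> float:
    """m6A sample index: summed normalized IP coverage over all site windows
    divided by the corresponding input sum.  Tracks are dicts gene -> array."""
    if not sites:
        raise ValueError("site list must be nonempty")
    num = den = 0.0
    for s in sites:
        half = window // 2
        ip = ip_tracks[s.gene]
        inp = input_tracks[s.gene]
        lo, hi = max(0, s.summit - half), min(len(ip), s.summit + half + 1)
        num += float(np.sum(ip[lo:hi]))
        den += float(np.sum(inp[lo:hi]))
    if den == 0:
        raise ValueError("zero input coverage over sites")
    return num / den


def gene_index(ip_reads: float, input_reads: float,
               ip_libsize: float = 1.0, input_libsize: float = 1.0) -> float | None:
    """m6A gene index: library-normalized IP/input read ratio for one gene."""
    if input_reads <= 0:
        return None
    return (ip_reads / ip_libsize) / (input_reads / input_libsize)


def _restrict_fragments(fragments, motif_a: int, variant_positions) -> list:
    out = []
    vp = set(int(v) for v in variant_positions)
    for start, end in fragments:
        if not (start <= motif_a < end):
            continue
        if any(start <= v < end for v in vp):
            continue
        out.append((start, end))
    return out


def fragment_coverage(fragments, length: int) -> np.ndarray:
    """Pileup of half-open fragment intervals via boundary differences."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for start, end in fragments:
        diff[max(0, start)] += 1
        diff[min(length, end)] -= 1
    return np.cumsum(diff[:-1])


def ident_score(
    ip_fragments, input_fragments, motif_a: int, variant_positions,
    gene_length: int, window: int = 81,
) -> float | None:
    """score1 restricted to fragments identical between alleles.

    Only fragments that cover the motif A and overlap no variant position are
    piled up; score1 is then computed on the restricted coverage.  None when
    no qualifying fragments remain in either fraction.
    """
    ip_keep = _restrict_fragments(ip_fragments, motif_a, variant_positions)
    input_keep = _restrict_fragments(input_fragments, motif_a, variant_positions)
    if not ip_keep or not input_keep:
        return None
    ip_cov = fragment_coverage(ip_keep, gene_length)
    input_cov = fragment_coverage(input_keep, gene_length)
    return score1(ip_cov, input_cov, motif_a, window)


def cpm_normalize(tracks: dict) -> dict:
    """Scale a {gene: coverage array} track set to counts per million."""
    total = sum(float(np.sum(v)) for v in tracks.values())
    if total == 0:
        return {g: np.asarray(v, dtype=float) for g, v in tracks.items()}
    f = 1e6 / total
    return {g: np.asarray(v, dtype=float) * f for g, v in tracks.items()}


def call_peaks_gene(
    gene: str,
    sequence: str,
    ip_tracks: list[np.ndarray],
    input_tracks: list[np.ndarray],
    params: PeakCallParams,
) -> list[M6ASite]:
    """Run the filtering cascade for one gene (replicate lists of normalized
    coverage).  Window detection operates on the replicate-mean IP score2."""
    ip_s2 = [score2_profile(t, window=params.score2_window) for t in ip_tracks]
    if any(s is None for s in ip_s2):
        return []
    input_s2 = [score2_profile(t, window=params.score2_window) for t in input_tracks]
    if any(s is None for s in input_s2):
        return []
    mean_s2 = np.mean(ip_s2, axis=0)
    windows = detect_windows(mean_s2, params, gene=gene)
    windows = winscore_filter(windows, ip_s2, input_s2, params)
    aggregate = np.sum(ip_tracks, axis=0)
    sites = []
    for win in windows:
        summit, motif_a, dist = summit_and_motif(win, aggregate, sequence, params)
        win.summit = summit
        anchor = motif_a if motif_a is not None else summit
        per_rep = []
        for ip, inp in zip(ip_tracks, input_tracks):
            s1 = score1(ip, inp, anchor, params.score1_window)
            if s1 is None:
                break
            per_rep.append(s1)
        else:
            s1_agg = aggregate_score1(per_rep, params.score1_aggregate)
            if s1_agg > params.score1_threshold:
                sites.append(M6ASite(
                    gene=gene, summit=summit, motif_a_position=motif_a,
                    motif_distance=dist, score1=s1_agg,
                    score2_at_summit=float(mean_s2[summit]),
                    window=(win.start, win.end),
                ))
    return sites


def window_scores_for_ko(
    win: tuple[int, int],
    site: int,
    ip_tracks, input_tracks,
    params: PeakCallParams,
):
    """Per-replicate (score1, window-mean score2) pairs used by the KO filter."""
    s1s, s2s = [], []
    for ip, inp in zip(ip_tracks, input_tracks):
        s1 = score1(ip, inp, site, params.score1_window)
        s1s.append(s1 if s1 is not None else 0.0)
        prof = score2_profile(ip, window=params.score2_window)
        s2s.append(float(np.mean(prof[win[0]:win[1]])) if prof is not None else 0.0)
    return s1s, s2s
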