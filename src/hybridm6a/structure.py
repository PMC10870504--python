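"""Windowed RNA secondary-structure prediction around methylated adenosines.

Local secondary structure competes with methylation: a consensus motif buried
in a stem is poorly methylated, an open motif is accessible.  The analysis
folds an odd-length window (default 61 nt) centered on the methylated A of
each allele, takes the minimum free energy (MFE, kcal/mol) as the structure
score, and compares alleles through their MFE difference.  A site counts as
"solidly structured" when at least one allele folds below a threshold
(default -8 kcal/mol).

Two folding engines are provided.  The external engine uses the ViennaRNA
(RNAfold) nearest-neighbor model through its Python bindings when they are
importable.  The bundled engine is a deliberately simplified nearest-neighbor
model -- pair energies GC -3, AU -2, GU -1 kcal/mol, hairpin loops of at
least 3 nt, no lone pairs -- solved exactly by O(n^3) dynamic programming.
The bundled engine is self-contained and exhaustively verifiable, which the
test suite exploits by comparing it against full structure enumeration on
short sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_ENERGY = {
    "GC": -3.0, "CG": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}
MIN_HAIRPIN = 3
MIN_FOLD_LEN = 10

try:  # ViennaRNA python bindings
    import RNA as _vienna
except ImportError:  # pragma: no cover - depends on environment
    _vienna = None

ENGINE_EXTERNAL = "external-nearest-neighbor"
ENGINE_BUNDLED = "bundled-simplified"


@dataclass
class StructureParams:
    window: int = 61
    solid_structure_threshold: float = -8.0
    engine: str = "auto"
    #: rescaling applied to the threshold when the bundled engine is active;
    #: the -8 kcal/mol default is calibrated against the external model.
    bundled_threshold_factor: float = 1.0

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


@dataclass
class FoldResult:
    mfe: float
    structure: str
    engine: str

    def __post_init__(self):
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")
        if self.mfe > 0:
            raise ValueError("MFE must be <= 0")

    def pairs(self) -> set[tuple[int, int]]:
        stack, out = [], set()
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                out.add((stack.pop(), i))
        return out


def resolve_engine(engine: str = "auto") -> str:
    if engine == "auto":
        return ENGINE_EXTERNAL if _vienna is not None else ENGINE_BUNDLED
    if engine == ENGINE_EXTERNAL and _vienna is None:
        raise RuntimeError("ViennaRNA python bindings are not importable")
    if engine not in (ENGINE_EXTERNAL, ENGINE_BUNDLED):
        raise ValueError(f"unknown engine {engine!r}")
    return engine


def fold_mfe(sequence: str, engine: str = "auto") -> FoldResult:
    """Fold one RNA sequence and return its MFE and dot-bracket structure.

    Sequences shorter than 10 nt are unfoldable by convention (MFE 0).
    """
    sequence = sequence.upper().replace("T", "U")
    if any(b not in "ACGUN" for b in sequence):
        raise ValueError("sequence must be RNA (ACGU)")
    eng = resolve_engine(engine)
    if len(sequence) < MIN_FOLD_LEN:
        logger.debug("sequence of %d nt below fold minimum; MFE 0", len(sequence))
        return FoldResult(0.0, "." * len(sequence), eng)
    if eng == ENGINE_EXTERNAL:
        struct, mfe = _vienna.fold(sequence)
        return FoldResult(min(0.0, float(mfe)), struct, eng)
    return _fold_bundled(sequence)


def _fold_bundled(seq: str) -> FoldResult:
    """Exact DP for the simplified model.

    States over closed intervals [i, j]:
      P[i, j] -- minimum energy with (i, j) paired and (i+1, j-1) paired,
                 i.e. (i, j) opens a helix of length >= 2 (no lone pairs);
      Wne[i, j] -- minimum energy over structures on [i, j] containing at
                 least one helix;
      W = min(0, Wne) -- the unconstrained optimum (empty structure allowed).

    P(i,j) = e(i,j) + min( P(i+1,j-1),
                           e(i+1,j-1) + L(i+2,j-2) )
    where L is the content closed by the innermost pair of the helix: either
    an all-unpaired hairpin loop of >= MIN_HAIRPIN nt, or any structure with
    further helices (Wne).
    """
    n = len(seq)
    INF = float("inf")
    e = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + 1, n):
            en = PAIR_ENERGY.get(seq[i] + seq[j])
            if en is not None:
                e[i, j] = en

    P = np.full((n, n), INF)
    Wne = np.full((n + 1, n + 1), INF)  # index by [i, j] closed; j < i empty
    W = np.zeros((n + 1, n + 1))

    def L(a, b):
        # interior closed by the innermost helix pair (a-1, b+1)
        hairpin = 0.0 if (b - a + 1) >= MIN_HAIRPIN else INF
        inner = Wne[a, b] if a <= b else INF
        return min(hairpin, inner)

    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if e[i, j] < INF and j - i >= 2 and e[i + 1, j - 1] < INF:
                stack_on = P[i + 1, j - 1] if j - i >= 4 else INF
                close = e[i + 1, j - 1] + L(i + 2, j - 2)
                P[i, j] = e[i, j] + min(stack_on, close)
        # Wne over [i, j]: either i unpaired, or i pairs with k (helix start)
        row_p = P[i]
        for j in range(i, n):
            best = Wne[i + 1, j] if i + 1 <= j else INF
            ks = np.arange(i + 1, j + 1)
            if len(ks):
                cand = row_p[ks] + W[ks + 1, j]
                m = cand.min() if len(cand) else INF
                best = min(best, m)
            Wne[i, j] = best
            W[i, j] = min(0.0, best)

    mfe = float(W[0, n - 1])
    struct = ["."] * n
    _traceback(seq, e, P, Wne, W, struct, 0, n - 1, "W")
    return FoldResult(min(0.0, mfe), "".join(struct), ENGINE_BUNDLED)


def _traceback(seq, e, P, Wne, W, struct, i, j, state):
    INF = float("inf")
    while True:
        if i >= j:
            return
        if state == "W":
            if W[i, j] >= 0.0:
                return
            state = "Wne"
            continue
        if state == "Wne":
            if i + 1 <= j and Wne[i + 1, j] == Wne[i, j]:
                i += 1
                continue
            for k in range(i + 1, j + 1):
                if P[i, k] < INF and P[i, k] + W[k + 1, j] == Wne[i, j]:
                    _traceback(seq, e, P, Wne, W, struct, i, k, "P")
                    i, state = k + 1, "W"
                    break
            else:
                return
            continue
        if state == "P":
            struct[i], struct[j] = "(", ")"
            target = P[i, j] - e[i, j]
            if j - i >= 4 and P[i + 1, j - 1] == target:
                i, j = i + 1, j - 1
                continue
            # innermost pair of the helix
            struct[i + 1], struct[j - 1] = "(", ")"
            a, b = i + 2, j - 2
            if a <= b and Wne[a, b] == target - e[i + 1, j - 1]:
                i, j, state = a, b, "Wne"
                continue
            return


def delta_mfe(
    seq_a: str,
    seq_b: str,
    center_a: int,
    allele_map=None,
    params: StructureParams | None = None,
) -> tuple[float, float, float] | None:
    """MFE(window in A) - MFE(window in B) for homologous windows centered on
    the methylated A.  Returns (mfe_a, mfe_b, delta) or None when the center
    cannot be mapped to allele B.
    """
    params = params or StructureParams()
    if allele_map is None:
        center_b = center_a
    else:
        center_b = allele_map.map_position(center_a, direction="A2B")
        if center_b is None:
            return None
    win_a = extract_window(seq_a, center_a, params.window)
    win_b = extract_window(seq_b, center_b, params.window)
    mfe_a = fold_mfe(win_a, params.engine).mfe
    mfe_b = fold_mfe(win_b, params.engine).mfe
    return mfe_a, mfe_b, mfe_a - mfe_b


def extract_window(sequence: str, center: int, window: int) -> str:
    """Odd window centered on ``center``, truncated at sequence bounds."""
    half = window // 2
    lo = max(0, center - half)
    hi = min(len(sequence), center + half + 1)
    return sequence[lo:hi]


def effective_threshold(params: StructureParams) -> float:
    if resolve_engine(params.engine) == ENGINE_BUNDLED:
        return params.solid_structure_threshold * params.bundled_threshold_factor
    return params.solid_structure_threshold


def structure_filter(
    site_table: pd.DataFrame,
    params: StructureParams | None = None,
) -> pd.DataFrame:
    """Subset of sites suitable for structure attribution.

    Requires columns ``mfe_a``, ``mfe_b`` and boolean ``motif_disrupted``.
    Retains sites without motif-damaging substitutions whose more structured
    allele folds strictly below the solid-structure threshold.
    """
    params = params or StructureParams()
    thr = effective_threshold(params)
    keep = (~site_table["motif_disrupted"].astype(bool)) & (
        np.minimum(site_table["mfe_a"], site_table["mfe_b"]) < thr
    )
    return site_table[keep]


POSITION_BINS = [
    "5' UTR",
    "CDS adjacent to 5' UTR",
    "CDS",
    "CDS adjacent to 3' UTR",
    "3' UTR",
]


def positional_bin(pos: int, utr5_end: int, cds_end: int, gene_len: int) -> str:
    """Assign one of five positional bins from a gene model.

    The gene model is 0-based half-open: 5'UTR = [0, utr5_end), CDS =
    [utr5_end, cds_end), 3'UTR = [cds_end, gene_len).  The first and last 10%
    of the CDS form their own bins.
    """
    if pos < utr5_end:
        return POSITION_BINS[0]
    if pos >= cds_end:
        return POSITION_BINS[4]
    cds_len = cds_end - utr5_end
    frac = (pos - utr5_end) / cds_len
    if frac < 0.10:
        return POSITION_BINS[1]
    if frac >= 0.90:
        return POSITION_BINS[3]
    return POSITION_BINS[2]


def position_structure_binning(
    motif_table: pd.DataFrame,
    params: StructureParams | None = None,
) -> pd.DataFrame:
    """5 x 4 table of percent-methylated motifs.

    ``motif_table`` needs columns ``position_bin`` (one of POSITION_BINS),
    ``mfe`` (window MFE at the motif) and boolean ``methylated``.  MFE values
    are split into quartiles (Q1 = most structured); each cell is the
    percentage of motifs in that (positional bin, MFE quartile) that are
    methylated.
    """
    df = motif_table.copy()
    df["mfe_quartile"] = pd.qcut(
        df["mfe"], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop"
    )
    table = (
        df.groupby(["position_bin", "mfe_quartile"], observed=False)["methylated"]
        .mean()
        .unstack()
        .reindex(POSITION_BINS)
        * 100.0
    )
    return table
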