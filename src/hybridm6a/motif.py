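"""Consensus-motif analysis around methylated adenosines.

The methylation consensus is DRAC in yeast (D = A/G/U, R = A/G, with the
methylated A as the third base) and DRACH in mammals (H = A/C/U).  Beyond the
core motif, the surrounding positions -4..+4 (0 = methylated A) carry
information: specific substitutions at positions -4, -2, -1, 0, +1 and +4
(plus +2 in mammals) are known to disrupt methylation.  This module provides
motif scanning, the disruption table, context extraction, emerged-motif
counting, position frequency matrices for logos, and the evolutionary
coefficient score that ranks positions by how much more often they are
mutated at differentially methylated sites than at conserved ones.

Coordinates are 0-based; a "motif A position" is always the index of the
methylated adenosine itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_BASES = "ACGU"

#: allowed bases per offset relative to the methylated A (offset 0)
_MOTIF_OFFSETS = {
    "DRAC": {-2: "AGU", -1: "AG", 0: "A", 1: "C"},
    "DRACH": {-2: "AGU", -1: "AG", 0: "A", 1: "C", 2: "ACU"},
}

#: motif pattern per organism mode
MODE_MOTIF = {"yeast": "DRAC", "mammal": "DRACH"}

# Disruptive substitutions (position relative to methylated A, from-base,
# to-base).  The yeast set covers positions -4, -2, -1, 0, +1 and +4; the
# mammalian set additionally treats any base turning into G at +2 as
# disruptive.
_YEAST_DISRUPTIONS = frozenset(
    [(-4, "A", b) for b in "CGU"]
    + [(-2, "G", b) for b in "ACU"]
    + [(-2, "A", b) for b in "CU"]
    + [(-2, "U", "C")]
    + [(-1, "G", b) for b in "ACU"]
    + [(-1, "A", b) for b in "CU"]
    + [(0, "A", b) for b in "CGU"]
    + [(1, "C", b) for b in "AGU"]
    + [(4, "U", b) for b in "ACG"]
)

_MAMMAL_DISRUPTIONS = _YEAST_DISRUPTIONS | frozenset((2, b, "G") for b in "ACU")

CONTEXT_OFFSETS = tuple(range(-4, 5))


def motif_pattern(mode: str) -> str:
    """Return the consensus pattern name ('DRAC' or 'DRACH') for a mode."""
    try:
        return MODE_MOTIF[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; expected 'yeast' or 'mammal'")


def disruption_table(mode: str) -> frozenset:
    """The set of (offset, from_base, to_base) motif-disrupting substitutions."""
    if mode == "yeast":
        return _YEAST_DISRUPTIONS
    if mode == "mammal":
        return _MAMMAL_DISRUPTIONS
    raise ValueError(f"unknown mode {mode!r}")


def serialize_disruption_table(mode: str) -> pd.DataFrame:
    """Disruption table as a sorted DataFrame (offset, from_base, to_base)."""
    rows = sorted(disruption_table(mode))
    return pd.DataFrame(rows, columns=["offset", "from_base", "to_base"])


def parse_disruption_table(df: pd.DataFrame) -> frozenset:
    return frozenset(
        (int(r.offset), str(r.from_base), str(r.to_base)) for r in df.itertuples()
    )


def find_motif_positions(sequence: str, pattern: str = "DRAC") -> list[int]:
    """0-based positions of the methylated A of every motif match."""
    offsets = _MOTIF_OFFSETS[pattern]
    lo, hi = min(offsets), max(offsets)
    out = []
    for a in range(-lo, len(sequence) - hi):
        if all(sequence[a + off] in allowed for off, allowed in offsets.items()):
            out.append(a)
    return out


def is_motif_at(sequence: str, a_position: int, pattern: str = "DRAC") -> bool:
    offsets = _MOTIF_OFFSETS[pattern]
    for off, allowed in offsets.items():
        p = a_position + off
        if p < 0 or p >= len(sequence) or sequence[p] not in allowed:
            return False
    return True


@dataclass(frozen=True)
class MotifContext:
    """The 9-nt window (offsets -4..+4) around a methylated adenosine.

    ``window`` uses '-' for positions falling outside the gene or made
    unalignable by an indel in the homologous allele.
    """

    gene: str
    a_position: int
    window: str

    def __post_init__(self):
        if len(self.window) != 9:
            raise ValueError("context window must be 9 nt (offsets -4..+4)")


def extract_context(sequence: str, a_position: int, gene: str = "") -> MotifContext:
    chars = []
    for off in CONTEXT_OFFSETS:
        p = a_position + off
        chars.append(sequence[p] if 0 <= p < len(sequence) else "-")
    return MotifContext(gene=gene, a_position=a_position, window="".join(chars))


def is_motif_disrupting(
    context_methylated: MotifContext,
    context_other: MotifContext,
    mode: str = "yeast",
) -> tuple[bool, list[tuple[int, str, str]]]:
    """Directional disruption check from the methylated allele to the other.

    Returns ``(flag, hits)`` where hits lists the (offset, from, to) entries
    found in the disruption table.  A gap ('-') at any tabulated position is
    treated as disrupting and reported with to_base '-' (the "unalignable"
    label).
    """
    table = disruption_table(mode)
    tabulated_offsets = {off for off, _, _ in table}
    hits = []
    for i, off in enumerate(CONTEXT_OFFSETS):
        b_from = context_methylated.window[i]
        b_to = context_other.window[i]
        if b_from == b_to:
            continue
        if "-" in (b_from, b_to):
            if off in tabulated_offsets:
                hits.append((off, b_from, "-"))
            continue
        if (off, b_from, b_to) in table:
            hits.append((off, b_from, b_to))
    return bool(hits), hits


def count_motifs_in_window(
    sequence: str,
    center: int,
    halfwidth: int = 30,
    pattern: str = "DRAC",
) -> list[int]:
    """Motif A-positions within ``center ± halfwidth`` (absolute coordinates)."""
    lo = max(0, center - halfwidth)
    hi = min(len(sequence), center + halfwidth + 1)
    return [
        a for a in find_motif_positions(sequence, pattern) if lo <= a < hi
    ]


def emerged_motifs(
    seq_a: str,
    seq_b: str,
    center_b: int,
    allele_map,
    halfwidth: int = 30,
    pattern: str = "DRAC",
) -> int | None:
    """Count motifs in allele B's window that are absent at the homologous
    position in allele A.

    ``allele_map`` maps B coordinates to A coordinates (an
    :class:`~hybridm6a.homology.AlleleMap` used in the B→A direction).  A
    motif is *emerged* when its A-position either does not map, or maps to a
    position in A that is not a motif A.  Returns ``None`` when the window
    center itself is unmappable.
    """
    if allele_map.map_position(center_b, direction="B2A") is None:
        return None
    n = 0
    for a_pos_b in count_motifs_in_window(seq_b, center_b, halfwidth, pattern):
        hom = allele_map.map_position(a_pos_b, direction="B2A")
        if hom is None or not is_motif_at(seq_a, hom, pattern):
            n += 1
    return n


def consensus_matrix(sites: list[MotifContext]) -> pd.DataFrame:
    """Column-stochastic position frequency matrix over offsets -4..+4.

    Rows are bases A/C/G/U, columns are offsets.  Gap characters are
    ignored; each column is normalized over the observed bases, so columns
    sum to 1 (suitable for sequence logos).
    """
    if not sites:
        raise ValueError("need at least one site")
    counts = np.zeros((len(RNA_BASES), len(CONTEXT_OFFSETS)))
    for ctx in sites:
        for j, base in enumerate(ctx.window):
            if base in RNA_BASES:
                counts[RNA_BASES.index(base), j] += 1
    colsum = counts.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return pd.DataFrame(counts / colsum, index=list(RNA_BASES),
                        columns=list(CONTEXT_OFFSETS))


@dataclass
class CoefficientResult:
    """Positionwise mutation-enrichment coefficients, scaled to [-1, +1]."""

    mismatch_rate_dm: pd.Series
    mismatch_rate_invariable: pd.Series
    raw_reduction: pd.Series
    coefficient: pd.Series
    base_ratio: pd.DataFrame = field(repr=False)


def _mismatch_rates(pairs, pseudocount):
    n = len(pairs)
    rates = {}
    counts = {}
    for off in CONTEXT_OFFSETS:
        i = CONTEXT_OFFSETS.index(off)
        c = sum(
            1
            for meth, other in pairs
            if meth.window[i] != other.window[i]
            and meth.window[i] in RNA_BASES
            and other.window[i] in RNA_BASES
        )
        counts[off] = c
        rates[off] = (c + pseudocount) / (n + pseudocount)
    return pd.Series(rates), counts


def coefficient_scores(
    dm_sites: list[tuple[MotifContext, MotifContext]],
    invariable_sites: list[tuple[MotifContext, MotifContext]],
    pseudocount: float = 1.0,
) -> CoefficientResult:
    """Relative essentiality of each position for methylation.

    For every position around the motif we compute the mismatch frequency in
    the differentially methylated set and in the invariable (conserved) set;
    the invariable set serves as the neutral baseline.  The raw reduction
    r(p) = f_DM(p) - f_inv(p) is mean-centered and scaled by its maximum
    absolute value so coefficients span [-1, +1]; positions essential for
    methylation come out near +1.  A per-base (from→to) pseudocounted ratio
    matrix between the two sets is reported alongside.
    """
    if not dm_sites or not invariable_sites:
        raise ValueError("both site sets must be nonempty")
    f_dm, c_dm = _mismatch_rates(dm_sites, pseudocount)
    f_inv, c_inv = _mismatch_rates(invariable_sites, pseudocount)
    r = f_dm - f_inv
    centered = r - r.mean()
    scale = centered.abs().max()
    coeff = centered / scale if scale > 0 else centered * 0.0

    def _base_counts(pairs):
        counts = {}
        for meth, other in pairs:
            for i, off in enumerate(CONTEXT_OFFSETS):
                x, y = meth.window[i], other.window[i]
                if x != y and x in RNA_BASES and y in RNA_BASES:
                    counts[(off, x, y)] = counts.get((off, x, y), 0) + 1
        return counts

    bc_dm = _base_counts(dm_sites)
    bc_inv = _base_counts(invariable_sites)
    rows = []
    for off in CONTEXT_OFFSETS:
        for x in RNA_BASES:
            for y in RNA_BASES:
                if x == y:
                    continue
                num = bc_dm.get((off, x, y), 0) + pseudocount
                den = bc_inv.get((off, x, y), 0) + pseudocount
                rows.append((off, x, y, num / den))
    base_ratio = pd.DataFrame(rows, columns=["offset", "from_base", "to_base", "ratio"])
    return CoefficientResult(
        mismatch_rate_dm=f_dm,
        mismatch_rate_invariable=f_inv,
        raw_reduction=r,
        coefficient=coeff,
        base_ratio=base_ratio,
    )
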