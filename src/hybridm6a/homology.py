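"""Homologous-coordinate maps between the two alleles of a gene.

Positions called on one allele must be transferred to the other before any
cross-allele comparison.  We build a monotone block map from an affine-gap
pairwise alignment (Smith-Waterman for local mode, Needleman-Wunsch for
global mode) with EMBOSS-style scoring: match +5 / mismatch -4, and a gap of
length L costing ``gap_open + L * gap_extend`` (defaults 10 and 0.5).  The
dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module owns the parameter translation, the block-map representation and
coordinate transfer, plus a concordance check between two independently
produced maps.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio import Align


@dataclass
class AlignParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: str = "local"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")


@dataclass
class AlleleMap:
    """Monotone homologous-coordinate map as aligned blocks.

    Each block is ``(start_a, start_b, length)``; blocks are strictly
    increasing and non-overlapping in both coordinates.  Positions between
    blocks (gaps) are unmappable.
    """

    blocks: list[tuple[int, int, int]] = field(default_factory=list)
    score: float = 0.0

    def __post_init__(self):
        prev_a = prev_b = -1
        for a, b, ln in self.blocks:
            if ln <= 0 or a <= prev_a or b <= prev_b:
                raise ValueError("blocks must be increasing, non-overlapping")
            prev_a, prev_b = a + ln - 1, b + ln - 1

    def map_position(self, pos: int, direction: str = "A2B") -> int | None:
        """Translate one coordinate; None when the position is in a gap or
        outside the aligned span."""
        if direction == "A2B":
            starts = [blk[0] for blk in self.blocks]
            src, dst = 0, 1
        elif direction == "B2A":
            starts = [blk[1] for blk in self.blocks]
            src, dst = 1, 0
        else:
            raise ValueError("direction must be 'A2B' or 'B2A'")
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        blk = self.blocks[i]
        off = pos - blk[src]
        if off >= blk[2]:
            return None
        return blk[dst] + off

    def invert(self) -> "AlleleMap":
        return AlleleMap(
            blocks=[(b, a, ln) for a, b, ln in self.blocks], score=self.score
        )

    def mapped_positions_a(self):
        for a, _, ln in self.blocks:
            yield from range(a, a + ln)

    def to_chain(self, name_a: str = "A", len_a: int = 0,
                 name_b: str = "B", len_b: int = 0) -> str:
        """Export as a UCSC chain record (plus-strand, single chain)."""
        if not self.blocks:
            return ""
        a0, b0, _ = self.blocks[0]
        a_end = self.blocks[-1][0] + self.blocks[-1][2]
        b_end = self.blocks[-1][1] + self.blocks[-1][2]
        lines = [
            f"chain {int(self.score)} {name_a} {len_a} + {a0} {a_end} "
            f"{name_b} {len_b} + {b0} {b_end} 1"
        ]
        for i, (a, b, ln) in enumerate(self.blocks):
            if i + 1 < len(self.blocks):
                na, nb, _ = self.blocks[i + 1]
                lines.append(f"{ln}\t{na - (a + ln)}\t{nb - (b + ln)}")
            else:
                lines.append(str(ln))
        return "\n".join(lines) + "\n"


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = params.mode
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # EMBOSS convention: gap of length L costs open + L*extend.  Biopython
    # charges open_gap_score on the first gap column and extend_gap_score on
    # each subsequent one.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_homologs(seq_a: str, seq_b: str,
                   params: AlignParams | None = None) -> AlleleMap:
    """Affine-gap pairwise alignment of two allele sequences as a block map.

    Local mode with no positive-scoring alignment yields an empty map.
    """
    params = params or AlignParams()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = _make_aligner(params)
    alignments = aligner.align(seq_a, seq_b)
    try:
        aln = alignments[0]
    except IndexError:
        return AlleleMap(blocks=[], score=0.0)
    if params.mode == "local" and aln.score <= 0:
        return AlleleMap(blocks=[], score=0.0)
    blocks = []
    ranges_a, ranges_b = aln.aligned
    for (a0, a1), (b0, _) in zip(ranges_a, ranges_b):
        blocks.append((int(a0), int(b0), int(a1 - a0)))
    return AlleleMap(blocks=blocks, score=float(aln.score))


def cross_validate_maps(map1: AlleleMap, map2: AlleleMap,
                        positions_a: list[int]) -> dict[int, bool]:
    """Per-position concordance of two independently derived maps.

    A position agrees when both maps translate it to the same coordinate
    (both-unmappable counts as discordant only if exactly one map covers it;
    two Nones agree).  Discordant positions should be excluded downstream.
    """
    out = {}
    for p in positions_a:
        out[p] = map1.map_position(p) == map2.map_position(p)
    return out
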