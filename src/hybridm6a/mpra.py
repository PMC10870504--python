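"""Reporter-oligo design and analysis for structure-perturbation assays.

Each reporter insert is a 101-nt sequence carrying a single DRACH motif and
an engineered hairpin: a 21-bp perfect stem with an 11-nt loop.  In 1-based
insert coordinates the upstream arm spans [30, 50], the loop [51, 61] and
the downstream arm [62, 82]; arm position 30+k pairs with 82-k.  The
stem-shift series moves the methylated A from the middle of the loop
(position 56, fully single-stranded motif) into the middle of the stem
(position 72, fully paired motif) in 1-nt steps, 17 designs per site.
Point-mutant (DRACH -> DRTCH) and QTL ref/alt designs reuse the same insert
geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import motif as motif_mod

logger = logging.getLogger(__name__)

INSERT_LEN = 101
ARM_UP = (30, 50)     # 1-based inclusive
LOOP = (51, 61)
ARM_DOWN = (62, 82)
SHIFT_POSITIONS = tuple(range(56, 73))
STEM_LEN = ARM_UP[1] - ARM_UP[0] + 1

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: deterministic preference when a base must be changed
_BASE_ORDER = "ACGU"


@dataclass
class OligoDesign:
    site_id: str
    variant_id: str
    sequence: str
    design_kind: str           # stem_shift | point_mutant | qtl_ref | qtl_alt
    shift_position: int | None = None

    def __post_init__(self):
        if len(self.sequence) != INSERT_LEN:
            raise ValueError("insert must be 101 nt")

    @property
    def hairpin(self):
        return {"upstream_arm": ARM_UP, "loop": LOOP, "downstream_arm": ARM_DOWN}

    def to_dna(self) -> str:
        return self.sequence.replace("U", "T")


def _partner(pos: int) -> int | None:
    """1-based stem partner of a 1-based position, or None outside the arms."""
    if ARM_UP[0] <= pos <= ARM_UP[1]:
        return ARM_DOWN[1] - (pos - ARM_UP[0])
    if ARM_DOWN[0] <= pos <= ARM_DOWN[1]:
        return ARM_UP[0] + (ARM_DOWN[1] - pos)
    return None


def paired_motif_fraction(shift_position: int) -> float:
    """Fraction of the 5 DRACH bases that lie inside the stem arms."""
    bases = range(shift_position - 2, shift_position + 3)
    n = sum(1 for b in bases if _partner(b) is not None)
    return n / 5.0


def arm_pairing_ok(sequence: str) -> bool:
    """Brute-force check that the two arms are reverse-complementary
    base-by-base."""
    for k in range(STEM_LEN):
        u = sequence[ARM_UP[0] - 1 + k]
        d = sequence[ARM_DOWN[1] - 1 - k]
        if _COMP[u] != d:
            return False
    return True


def _find_single_motif(sequence: str, pattern: str = "DRACH") -> int:
    hits = motif_mod.find_motif_positions(sequence, pattern)
    if len(hits) != 1:
        raise ValueError(f"expected exactly one {pattern}, found {len(hits)}")
    return hits[0]


def _extra_motifs(seq: list, keep_a0: int, pattern: str) -> list[int]:
    return [
        a for a in motif_mod.find_motif_positions("".join(seq), pattern)
        if a != keep_a0
    ]


def _design_one(original: str, site_id: str, p: int,
                pattern: str = "DRACH") -> OligoDesign | None:
    """Build one stem-shift design with the methylated A at 1-based p."""
    a0_orig = _find_single_motif(original, pattern)
    motif5 = original[a0_orig - 2:a0_orig + 3]
    seq = list(original)
    a0 = p - 1  # 0-based A position
    motif_range = set(range(a0 - 2, a0 + 3))            # 0-based
    seq[a0 - 2:a0 + 3] = list(motif5)

    # enforce perfect arm complementarity, deferring to motif bases
    partner_of_motif = set()
    for k in range(STEM_LEN):
        u0 = ARM_UP[0] - 1 + k
        d0 = ARM_DOWN[1] - 1 - k
        if u0 in motif_range:
            seq[d0] = _COMP[seq[u0]]
            partner_of_motif.add(d0)
        elif d0 in motif_range:
            seq[u0] = _COMP[seq[d0]]
            partner_of_motif.add(u0)
        else:
            seq[d0] = _COMP[seq[u0]]

    frozen = motif_range | partner_of_motif

    def _apply(q0: int, base: str) -> list[int] | None:
        """Try seq[q0] = base (with partner update); return affected indices
        or None if not allowed."""
        if q0 in frozen:
            return None
        partner = _partner(q0 + 1)
        idx = [q0]
        if partner is not None:
            p0 = partner - 1
            if p0 in frozen:
                return None
            idx.append(p0)
        return idx

    for _round in range(20):
        extras = _extra_motifs(seq, a0, pattern)
        if not extras:
            break
        fixed = False
        for extra_a in extras:
            # candidate positions: the spurious motif's core, A first
            candidates = [extra_a] + [extra_a + off for off in (-2, -1, 1, 2)]
            for q0 in candidates:
                if not (0 <= q0 < INSERT_LEN):
                    continue
                idx = _apply(q0, "")
                if idx is None:
                    continue
                current = seq[q0]
                for base in _BASE_ORDER:
                    if base == current:
                        continue
                    saved = {i: seq[i] for i in idx}
                    seq[q0] = base
                    partner = _partner(q0 + 1)
                    if partner is not None:
                        seq[partner - 1] = _COMP[base]
                    new_extras = _extra_motifs(seq, a0, pattern)
                    if (len(new_extras) < len(extras)
                            and motif_mod.is_motif_at("".join(seq), a0, pattern)):
                        fixed = True
                        break
                    for i, b in saved.items():
                        seq[i] = b
                if fixed:
                    break
            if fixed:
                break
        if not fixed:
            logger.warning("site %s position %d: irreparable extra motif; "
                           "skipped", site_id, p)
            return None
    else:
        return None

    design = OligoDesign(
        site_id=site_id,
        variant_id=f"{site_id}_shift{p}",
        sequence="".join(seq),
        design_kind="stem_shift",
        shift_position=p,
    )
    assert arm_pairing_ok(design.sequence)
    return design


def design_stem_shift(
    site_sequences: dict,
    positions=SHIFT_POSITIONS,
    pattern: str = "DRACH",
) -> tuple[list[OligoDesign], list[str]]:
    """Stem-shift series for each site: one design per shift position.

    ``site_sequences`` maps site id -> 101-nt sequence containing a single
    DRACH.  Returns (designs, skipped site ids); a site is skipped entirely
    if any of its positions cannot be repaired to a single-DRACH insert.
    """
    designs, skipped = [], []
    for site_id, seq in site_sequences.items():
        seq = seq.upper().replace("T", "U")
        if len(seq) != INSERT_LEN:
            raise ValueError(f"site {site_id}: insert must be {INSERT_LEN} nt")
        series = []
        for p in positions:
            d = _design_one(seq, site_id, p, pattern)
            if d is None:
                series = None
                break
            series.append(d)
        if series is None:
            skipped.append(site_id)
        else:
            designs.extend(series)
    return designs, skipped


def stem_pairs() -> list[tuple[int, int]]:
    """The 21 annotated stem pairs in 0-based coordinates."""
    return [(ARM_UP[0] - 1 + k, ARM_DOWN[1] - 1 - k) for k in range(STEM_LEN)]


def _frozen_positions(design: OligoDesign) -> set[int]:
    a0 = design.shift_position - 1
    fro = set(range(a0 - 2, a0 + 3))
    for q in list(fro):
        partner = _partner(q + 1)
        if partner is not None:
            fro.add(partner - 1)
    return fro


def enforce_hairpin_mfe(
    design: OligoDesign,
    engine: str = "bundled-simplified",
    pattern: str = "DRACH",
) -> OligoDesign | None:
    """Repair a stem-shift design until the annotated hairpin is its MFE
    structure.

    The minimally mutated design is kept when it already folds as annotated.
    Otherwise the arms outside the motif are rewritten as alternating G/C
    pairs and the flanks and loop outside the motif are set to adenosine:
    under the simplified energy model the inert flanks cannot pair at all,
    the lone-pair exclusion blocks single-U pairings, and register shifts of
    the alternating stem strictly lose pairs, so the designed stem becomes
    the unique MFE structure.  Returns None when even the rewritten insert
    fails (e.g. the motif content cannot be preserved).
    """
    from . import structure as structure_mod

    stem = stem_pairs()

    def _folds(sequence: str) -> bool:
        fr = structure_mod.fold_mfe(sequence, engine)
        pairs = fr.pairs()
        return all(p in pairs for p in stem)

    if _folds(design.sequence):
        return design
    seq = list(design.sequence)
    a0 = design.shift_position - 1
    frozen = _frozen_positions(design)
    for k in range(STEM_LEN):
        u, d = ARM_UP[0] - 1 + k, ARM_DOWN[1] - 1 - k
        if u in frozen or d in frozen:
            continue
        seq[u], seq[d] = ("G", "C") if k % 2 == 0 else ("C", "G")
    inert = (list(range(0, ARM_UP[0] - 1))
             + list(range(ARM_DOWN[1], INSERT_LEN))
             + list(range(LOOP[0] - 1, LOOP[1])))
    for q in inert:
        if q not in frozen:
            seq[q] = "A"
    repaired = "".join(seq)
    if motif_mod.find_motif_positions(repaired, pattern) != [a0]:
        logger.warning("%s: hairpin enforcement lost the single-motif "
                       "property", design.variant_id)
        return None
    if not _folds(repaired):
        return None
    return OligoDesign(
        site_id=design.site_id,
        variant_id=design.variant_id,
        sequence=repaired,
        design_kind=design.design_kind,
        shift_position=design.shift_position,
    )


def design_point_mutant(oligo: OligoDesign, pattern: str = "DRACH") -> OligoDesign:
    """DRACH -> DRTCH: replace the methylated A with U, all else unchanged."""
    a0 = _find_single_motif(oligo.sequence, pattern)
    seq = oligo.sequence[:a0] + "U" + oligo.sequence[a0 + 1:]
    return OligoDesign(
        site_id=oligo.site_id,
        variant_id=f"{oligo.variant_id}_mut",
        sequence=seq,
        design_kind="point_mutant",
        shift_position=oligo.shift_position,
    )


def analyze_shift_series(
    designs: list[OligoDesign],
    enrichment: dict,
) -> pd.DataFrame:
    """Per-position enrichment summary plus the pairing trend.

    ``enrichment`` maps variant id -> IP/input enrichment.  Returns a frame
    indexed by shift position with the median/mean enrichment, the paired
    fraction of the motif, and (as attrs) the Spearman correlation between
    median enrichment and paired fraction.
    """
    rows = {}
    for d in designs:
        if d.variant_id not in enrichment:
            continue
        rows.setdefault(d.shift_position, []).append(enrichment[d.variant_id])
    if not rows:
        raise ValueError("no enrichment values for any design")
    table = pd.DataFrame(
        {
            "median_enrichment": {p: float(np.median(v)) for p, v in rows.items()},
            "mean_enrichment": {p: float(np.mean(v)) for p, v in rows.items()},
            "n": {p: len(v) for p, v in rows.items()},
        }
    ).sort_index()
    table["paired_fraction"] = [paired_motif_fraction(p) for p in table.index]
    if len(table) > 1 and table["median_enrichment"].nunique() > 1:
        rho = stats.spearmanr(
            table["median_enrichment"], table["paired_fraction"]
        ).statistic
    else:
        rho = np.nan
    table.attrs["spearman_vs_paired_fraction"] = float(rho) if rho == rho else None
    return table


def simulate_shift_enrichment(
    designs: list[OligoDesign],
    scale: float = 8.0,
    floor: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Enrichment proportional to the unpaired fraction of the motif.

    A deterministic stand-in for reporter measurements: enrichment =
    floor + scale * (1 - paired_fraction), optionally with multiplicative
    log-normal noise.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for d in designs:
        e = floor + scale * (1.0 - paired_motif_fraction(d.shift_position))
        if noise_sd > 0:
            e *= float(rng.lognormal(0.0, noise_sd))
        out[d.variant_id] = e
    return out


def clustered_motif_compensation(
    wt_mut_pairs: pd.DataFrame,
    pattern: str = "DRACH",
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Correlation between signal depletion on motif loss and the number of
    additional motifs in the insert.

    ``wt_mut_pairs`` needs columns ``wt_sequence``, ``wt_enrichment`` and
    ``mut_enrichment``.  The extent of depletion is log2(WT / mut) (positive
    = stronger signal loss); the additional-motif count excludes the mutated
    consensus itself.  Inserts whose signal is buffered by clustered motifs
    lose less, so the expected correlation is negative.  Returns (pearson_r,
    p_value, annotated table); r is None when depletion has no variance.
    """
    if len(wt_mut_pairs) < 3:
        raise ValueError("need at least 3 WT/mutant pairs")
    df = wt_mut_pairs.copy()
    df["depletion"] = np.log2(df["wt_enrichment"] / df["mut_enrichment"])
    df["extra_motifs"] = [
        len(motif_mod.find_motif_positions(s.upper().replace("T", "U"), pattern)) - 1
        for s in df["wt_sequence"]
    ]
    if df["depletion"].nunique() < 2 or df["extra_motifs"].nunique() < 2:
        return None, None, df
    res = stats.pearsonr(df["extra_motifs"], df["depletion"])
    return float(res.statistic), float(res.pvalue), df
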