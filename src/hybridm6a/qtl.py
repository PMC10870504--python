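"""Mechanistic annotation of m6A quantitative trait loci.

An m6A-QTL is a genetic variant statistically associated with
inter-individual differences in methylation; its beta encodes the direction
of effect (positive: the alternative allele is more methylated).  Most
reported associations are not causal.  This module filters QTL tables down
to proximal, exonic, significant candidates and annotates the mechanism by
which a variant could act: creating or disrupting a consensus motif, or --
for motif-preserving variants -- changing local secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import motif as motif_mod
from . import structure as structure_mod

REQUIRED_COLUMNS = ("variant", "pvalue", "beta", "distance", "exonic")

#: proximity defaults: 50 nt for mechanism annotation, 30 nt for reporter
#: library selection
PROXIMITY_ANNOTATION = 50
PROXIMITY_REPORTER = 30


@dataclass
class QTLFilterParams:
    p_threshold: float = 0.01
    max_distance: int = PROXIMITY_ANNOTATION
    exonic_only: bool = True


def filter_proximal(qtls: pd.DataFrame,
                    params: QTLFilterParams | None = None) -> pd.DataFrame:
    """Putatively causal subset: strict p < threshold, within max_distance nt
    of the peak center, exonic (when requested)."""
    params = params or QTLFilterParams()
    if qtls.empty:
        return qtls
    keep = (qtls["pvalue"] < params.p_threshold) & (
        qtls["distance"] <= params.max_distance
    )
    if params.exonic_only:
        keep &= qtls["exonic"].astype(bool)
    return qtls[keep]


def annotate_motif_change(ref_window: str, alt_window: str,
                          mode: str = "mammal") -> str:
    """Compare motif content between ref and alt local sequence.

    Windows must be equal-length and centered on the variant (substitutions;
    windows containing indels should be rescanned and flagged upstream).
    Returns 'creates_motif', 'disrupts_motif', 'unchanged', or 'complex'
    when motifs are both lost and gained at different positions.
    """
    ref_window = ref_window.upper().replace("T", "U")
    alt_window = alt_window.upper().replace("T", "U")
    if len(ref_window) != len(alt_window):
        raise ValueError("windows must be equal length (indels not supported)")
    pattern = motif_mod.motif_pattern(mode)
    ref_set = set(motif_mod.find_motif_positions(ref_window, pattern))
    alt_set = set(motif_mod.find_motif_positions(alt_window, pattern))
    gained, lost = alt_set - ref_set, ref_set - alt_set
    if gained and lost:
        return "complex"
    if gained:
        return "creates_motif"
    if lost:
        return "disrupts_motif"
    return "unchanged"


def beta_consistency(annotated: pd.DataFrame):
    """Contingency of {creates, disrupts} x sign(beta) with Fisher's exact
    test.

    ``annotated`` needs columns ``motif_change`` and ``beta``.  Causal QTLs
    should show motif creation with positive beta (alternative allele more
    methylated) and disruption with negative beta.  Returns (2x2 table,
    odds_ratio, p) -- the test fields are None for degenerate tables.
    """
    if annotated.empty:
        raise ValueError("need at least one annotated record")
    df = annotated[annotated["motif_change"].isin(
        ["creates_motif", "disrupts_motif"])]
    table = pd.DataFrame(
        0, index=["creates_motif", "disrupts_motif"],
        columns=["beta_positive", "beta_negative"],
    )
    for _, row in df.iterrows():
        col = "beta_positive" if row["beta"] > 0 else "beta_negative"
        table.loc[row["motif_change"], col] += 1
    if len(df) < 2 or (table.values.sum(axis=1) == 0).any():
        return table, None, None
    odds, p = stats.fisher_exact(table.values)
    return table, float(odds), float(p)


def beta_class(beta: float) -> str:
    """Reference-exclusive (beta > 1), shared ([-1, 1]) or
    alternative-exclusive (beta < -1) methylation."""
    if beta > 1:
        return "ref_exclusive"
    if beta < -1:
        return "alt_exclusive"
    return "shared"


def qtl_structure_delta(
    qtls: pd.DataFrame,
    ref_windows: dict,
    alt_windows: dict,
    params: structure_mod.StructureParams | None = None,
) -> pd.DataFrame:
    """Per-QTL MFE difference (ref - alt) for motif-preserving variants,
    grouped by beta class.

    ``ref_windows``/``alt_windows`` map variant id -> sequence window
    centered on the methylated site.  QTLs with motif changes should be
    excluded beforehand; any present are dropped here.
    """
    params = params or structure_mod.StructureParams()
    rows = []
    for _, row in qtls.iterrows():
        v = row["variant"]
        if v not in ref_windows or v not in alt_windows:
            continue
        ref, alt = ref_windows[v], alt_windows[v]
        if annotate_motif_change(ref, alt) != "unchanged":
            continue
        mfe_ref = structure_mod.fold_mfe(ref, params.engine).mfe
        mfe_alt = structure_mod.fold_mfe(alt, params.engine).mfe
        rows.append({
            "variant": v,
            "beta": row["beta"],
            "beta_class": beta_class(row["beta"]),
            "mfe_ref": mfe_ref,
            "mfe_alt": mfe_alt,
            "delta_mfe": mfe_ref - mfe_alt,
            "solid": min(mfe_ref, mfe_alt)
            < structure_mod.effective_threshold(params),
        })
    return pd.DataFrame(
        rows, columns=["variant", "beta", "beta_class", "mfe_ref", "mfe_alt",
                       "delta_mfe", "solid"],
    )


def make_synthetic_qtls(
    n: int = 60,
    seed: int = 0,
    mode: str = "mammal",
    window: int = 61,
) -> tuple[pd.DataFrame, dict, dict]:
    """Synthetic causal QTL records with mechanism-forced beta signs.

    Half the records create a motif in the alternative allele (beta drawn
    positive), half disrupt the reference motif (beta negative).  Returns
    (records, ref_windows, alt_windows).  Intended for validating the
    annotation/association machinery; labelled synthetic throughout.
    """
    rng = np.random.default_rng(seed)
    pattern = motif_mod.motif_pattern(mode)
    rows, refw, altw = [], {}, {}
    half = window // 2
    for i in range(n):
        vid = f"snv{i:04d}"
        seq = ["ACGU"[b] for b in rng.integers(0, 4, window)]
        # clear any accidental motifs around the center
        core = "GGACU"
        disrupt = rng.random() < 0.5
        for k, b in enumerate(core):
            seq[half - 2 + k] = b
        ref = list(seq)
        alt = list(seq)
        if disrupt:
            alt[half] = "G"        # A -> G kills the motif in alt
            beta = -abs(rng.normal(1.5, 0.4))
        else:
            ref[half] = "G"        # motif exists only in alt
            beta = abs(rng.normal(1.5, 0.4))
        # remove other motif hits so exactly the planted one differs
        for s in (ref, alt):
            for a in motif_mod.find_motif_positions("".join(s), pattern):
                if a != half:
                    s[a] = "C"
        rows.append({
            "variant": vid, "position": half, "ref": "".join(ref[half]),
            "alt": "".join(alt[half]), "pvalue": float(rng.uniform(1e-6, 0.009)),
            "beta": float(beta), "peak": f"peak{i:04d}",
            "distance": int(rng.integers(0, 30)), "exonic": True,
        })
        refw[vid] = "".join(ref)
        altw[vid] = "".join(alt)
    return pd.DataFrame(rows), refw, altw
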