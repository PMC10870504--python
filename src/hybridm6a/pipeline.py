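"""End-to-end orchestration: simulate -> call peaks -> map -> classify ->
attribute -> report.

The pipeline ties the modules together on a synthetic hybrid experiment and
emits a per-site attribution report plus recovery metrics against the
planted truth.  Attribution precedence for differentially methylated cis
sites is explicit: a motif-disrupting substitution wins; otherwise a site
passing the solid-structure filter with |deltaMFE| above the margin is
attributed to structure; everything else is unexplained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cistrans, homology, io as io_mod, motif as motif_mod
from . import peakcall, simdata, structure as structure_mod
from .simdata import BACKGROUNDS, SampleKey

logger = logging.getLogger(__name__)

_MATCH_TOLERANCE = 5   # nt between called motif A and planted A to count as recovered
_MERGE_TOLERANCE = 3   # nt within which sites from different backgrounds merge


@dataclass
class RunConfig:
    simulation: simdata.SimulationConfig = field(
        default_factory=simdata.SimulationConfig)
    peaks: peakcall.PeakCallParams = field(
        default_factory=peakcall.PeakCallParams)
    classify: cistrans.ClassifyParams = field(
        default_factory=cistrans.ClassifyParams)
    structure: structure_mod.StructureParams = field(
        default_factory=structure_mod.StructureParams)
    align: homology.AlignParams = field(default_factory=homology.AlignParams)
    #: minimum |deltaMFE| (kcal/mol) for structure attribution
    attribution_margin: float = 2.0

    def __post_init__(self):
        self.peaks.motif = motif_mod.motif_pattern(self.simulation.mode)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        section_types = {
            "simulation": simdata.SimulationConfig,
            "peaks": peakcall.PeakCallParams,
            "classify": cistrans.ClassifyParams,
            "structure": structure_mod.StructureParams,
            "align": homology.AlignParams,
        }
        for name, typ in section_types.items():
            if name in raw:
                block = dict(raw[name])
                for key in ("gene_length_range", "fragment_length"):
                    if key in block:
                        block[key] = tuple(block[key])
                kwargs[name] = typ(**block)
        if "attribution_margin" in raw:
            kwargs["attribution_margin"] = float(raw["attribution_margin"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AttributionReport:
    sites: pd.DataFrame
    class_fractions: dict
    metrics: dict
    config_hash: str
    confusion: pd.DataFrame | None = None

    def checksum(self) -> str:
        blob = self.sites.round(6).to_csv(index=False) + json.dumps(
            self.class_fractions, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _normalized_tracks(exp: simdata.SimExperiment) -> dict:
    return {key: peakcall.cpm_normalize(tracks)
            for key, tracks in exp.coverage.items()}


def _replicate_tracks(norm, background, genotype, fraction, replicates):
    return [
        norm[SampleKey(background, genotype, fraction, rep)]
        for rep in range(replicates)
    ]


def _other_parent(background: str) -> str:
    return {
        "parent_a": "parent_b", "parent_b": "parent_a",
        "hybrid_a": "hybrid_b", "hybrid_b": "hybrid_a",
    }[background]


def call_peaks_all_backgrounds(
    exp: simdata.SimExperiment,
    params: peakcall.PeakCallParams,
    norm: dict | None = None,
) -> dict:
    """Per-background site lists after the full filtering cascade."""
    cfg = exp.config
    norm = norm or _normalized_tracks(exp)
    has_ko = cfg.ko_included
    sites_by_bg = {}
    for bg in BACKGROUNDS:
        allele = simdata.BACKGROUND_ALLELE[bg]
        seqs = (exp.genomes.sequences_a if allele == "a"
                else exp.genomes.sequences_b)
        ip = _replicate_tracks(norm, bg, "wt", "ip", cfg.replicates)
        inp = _replicate_tracks(norm, bg, "wt", "input", cfg.replicates)
        if has_ko:
            ip_ko = _replicate_tracks(norm, bg, "ko", "ip", cfg.replicates)
            inp_ko = _replicate_tracks(norm, bg, "ko", "input", cfg.replicates)
            other = _other_parent(bg)
            ip_o = _replicate_tracks(norm, other, "wt", "ip", cfg.replicates)
            inp_o = _replicate_tracks(norm, other, "wt", "input", cfg.replicates)
            ip_o_ko = _replicate_tracks(norm, other, "ko", "ip", cfg.replicates)
            inp_o_ko = _replicate_tracks(norm, other, "ko", "input", cfg.replicates)
        kept = []
        for gene in seqs:
            gene_ip = [t[gene] for t in ip]
            gene_inp = [t[gene] for t in inp]
            sites = peakcall.call_peaks_gene(
                gene, seqs[gene], gene_ip, gene_inp, params)
            for s in sites:
                if has_ko:
                    anchor = (s.motif_a_position
                              if s.motif_a_position is not None else s.summit)
                    wt1, wt2 = peakcall.window_scores_for_ko(
                        s.window, anchor, gene_ip, gene_inp, params)
                    ko1, ko2 = peakcall.window_scores_for_ko(
                        s.window, anchor,
                        [t[gene] for t in ip_ko], [t[gene] for t in inp_ko],
                        params)
                    o_wt1, _ = peakcall.window_scores_for_ko(
                        s.window, anchor,
                        [t[gene] for t in ip_o], [t[gene] for t in inp_o],
                        params)
                    o_ko1, _ = peakcall.window_scores_for_ko(
                        s.window, anchor,
                        [t[gene] for t in ip_o_ko], [t[gene] for t in inp_o_ko],
                        params)
                    ok, pval = peakcall.ko_filter(
                        wt1, ko1, wt2, ko2, params,
                        wt_scores1_other=o_wt1, ko_scores1_other=o_ko1)
                    s.ko_pass, s.ko_pvalue = ok, pval
                    if not ok:
                        continue
                kept.append(s)
        sites_by_bg[bg] = kept
    return sites_by_bg


def build_allele_maps(exp: simdata.SimExperiment,
                      params: homology.AlignParams) -> dict:
    return {
        gene: homology.align_homologs(
            exp.genomes.sequences_a[gene], exp.genomes.sequences_b[gene], params)
        for gene in exp.genomes.sequences_a
    }


def merge_sites(sites_by_bg: dict, maps: dict) -> pd.DataFrame:
    """Unify sites across backgrounds on allele-A coordinates."""
    records = []
    for bg, sites in sites_by_bg.items():
        allele = simdata.BACKGROUND_ALLELE[bg]
        for s in sites:
            pos = s.motif_a_position if s.motif_a_position is not None else s.summit
            if allele == "b":
                pos_a = maps[s.gene].map_position(pos, direction="B2A")
                if pos_a is None:
                    logger.info("site %s:%d unmappable to allele A; dropped",
                                s.gene, pos)
                    continue
            else:
                pos_a = pos
            records.append({
                "gene": s.gene, "pos_a": pos_a, "background": bg,
                "summit": s.summit, "allele_pos": pos,
                "motif_distance": s.motif_distance, "score1": s.score1,
            })
    if not records:
        return pd.DataFrame(
            columns=["gene", "pos_a", "backgrounds", "best_background",
                     "summit", "motif_distance"])
    df = pd.DataFrame(records).sort_values(["gene", "pos_a"])
    merged = []
    for gene, sub in df.groupby("gene"):
        cluster = []
        last = None
        for _, row in sub.iterrows():
            if last is not None and row["pos_a"] - last > _MERGE_TOLERANCE:
                merged.append(_collapse(gene, cluster))
                cluster = []
            cluster.append(row)
            last = row["pos_a"]
        if cluster:
            merged.append(_collapse(gene, cluster))
    return pd.DataFrame(merged)


def _collapse(gene, cluster) -> dict:
    best = max(cluster, key=lambda r: r["score1"])
    return {
        "gene": gene,
        "pos_a": int(best["pos_a"]),
        "backgrounds": ",".join(sorted({r["background"] for r in cluster})),
        "best_background": best["background"],
        "summit": int(best["summit"]),
        "motif_distance": best["motif_distance"],
    }


def score_sites_all_backgrounds(
    exp: simdata.SimExperiment,
    merged: pd.DataFrame,
    maps: dict,
    params: peakcall.PeakCallParams,
    norm: dict | None = None,
) -> pd.DataFrame:
    """Replicate-mean score1 for every merged site in all four backgrounds."""
    cfg = exp.config
    norm = norm or _normalized_tracks(exp)
    tracks = {
        bg: (
            _replicate_tracks(norm, bg, "wt", "ip", cfg.replicates),
            _replicate_tracks(norm, bg, "wt", "input", cfg.replicates),
        )
        for bg in BACKGROUNDS
    }
    out = merged.copy()
    for bg in BACKGROUNDS:
        allele = simdata.BACKGROUND_ALLELE[bg]
        col = []
        for _, row in merged.iterrows():
            gene, pos = row["gene"], int(row["pos_a"])
            if allele == "b":
                pos = maps[gene].map_position(pos, direction="A2B")
            if pos is None:
                col.append(0.0)
                continue
            ip, inp = tracks[bg]
            vals = [
                peakcall.score1(t[gene], u[gene], pos, params.score1_window)
                for t, u in zip(ip, inp)
            ]
            vals = [v for v in vals if v is not None]
            col.append(peakcall.aggregate_score1(vals) if vals else 0.0)
        out[f"score1_{bg}"] = col
    return out


def annotate_sites(
    exp: simdata.SimExperiment,
    scored: pd.DataFrame,
    maps: dict,
    run_config: RunConfig,
) -> pd.DataFrame:
    """Classification plus motif/structure attribution per merged site."""
    cfg = exp.config
    mode = cfg.mode
    df = cistrans.compare_sites(scored, run_config.classify)
    disrupted, hits_all, mfe_a_l, mfe_b_l, dmfe_l, attributions = \
        [], [], [], [], [], []
    for _, row in df.iterrows():
        gene, pos_a = row["gene"], int(row["pos_a"])
        amap = maps[gene]
        pos_b = amap.map_position(pos_a, direction="A2B")
        seq_a = exp.genomes.sequences_a[gene]
        seq_b = exp.genomes.sequences_b[gene]
        if pos_b is None:
            disrupted.append(True)
            hits_all.append("unalignable")
            mfe_a_l.append(np.nan)
            mfe_b_l.append(np.nan)
            dmfe_l.append(np.nan)
            attributions.append("motif")
            continue
        ctx_a = motif_mod.extract_context(seq_a, pos_a, gene)
        ctx_b = motif_mod.extract_context(seq_b, pos_b, gene)
        # disruption read from the methylated (higher hybrid score) allele
        if row["score1_hybrid_a"] >= row["score1_hybrid_b"]:
            flag, hits = motif_mod.is_motif_disrupting(ctx_a, ctx_b, mode)
        else:
            flag, hits = motif_mod.is_motif_disrupting(ctx_b, ctx_a, mode)
        disrupted.append(flag)
        hits_all.append(";".join(f"{o}:{f}>{t}" for o, f, t in hits))
        fold = structure_mod.delta_mfe(
            seq_a, seq_b, pos_a, amap, run_config.structure)
        if fold is None:
            mfe_a, mfe_b, dmfe = np.nan, np.nan, np.nan
        else:
            mfe_a, mfe_b, dmfe = fold
        mfe_a_l.append(mfe_a)
        mfe_b_l.append(mfe_b)
        dmfe_l.append(dmfe)
        if row["site_class"] != "DM-cis":
            attributions.append("none" if row["site_class"] == "invariable"
                                else "trans")
        elif flag:
            attributions.append("motif")
        else:
            thr = structure_mod.effective_threshold(run_config.structure)
            solid = (not np.isnan(dmfe)) and min(mfe_a, mfe_b) < thr
            if solid and abs(dmfe) > run_config.attribution_margin:
                attributions.append("structure")
            else:
                attributions.append("unexplained")
    df["motif_disrupted"] = disrupted
    df["disruption_hits"] = hits_all
    df["mfe_a"] = mfe_a_l
    df["mfe_b"] = mfe_b_l
    df["delta_mfe"] = dmfe_l
    df["attribution"] = attributions
    return df


_TRUTH_TO_CLASS = {
    "invariable": "invariable",
    "DM-cis-motif": "DM-cis",
    "DM-cis-structure": "DM-cis",
    "DM-trans": "DM-trans",
    "cis-trans": "cis-trans",
}


def evaluate_against_truth(exp: simdata.SimExperiment,
                           annotated: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Recovery metrics and a truth-vs-predicted class confusion matrix."""
    truth = exp.truth
    matched = []
    used = set()
    for t_idx, t in truth.iterrows():
        sub = annotated[annotated["gene"] == t["gene"]]
        best = None
        for idx, row in sub.iterrows():
            if idx in used:
                continue
            d = abs(int(row["pos_a"]) - int(t["a_position"]))
            if d <= _MATCH_TOLERANCE and (best is None or d < best[1]):
                best = (idx, d)
        if best is not None:
            used.add(best[0])
            matched.append((t_idx, best[0]))
    n_truth = len(truth)
    recall = len(matched) / n_truth if n_truth else float("nan")
    summit_ok = 0
    class_ok = 0
    attr_total = attr_ok = 0
    rows = []
    for t_idx, a_idx in matched:
        t = truth.loc[t_idx]
        a = annotated.loc[a_idx]
        if abs(int(a["summit"]) - int(t["a_position"])) <= 2:
            summit_ok += 1
        expected = _TRUTH_TO_CLASS[t["true_class"]]
        if a["site_class"] == expected:
            class_ok += 1
        rows.append((t["true_class"], a["site_class"]))
        if t["true_class"] in ("DM-cis-motif", "DM-cis-structure"):
            attr_total += 1
            want = "motif" if t["true_class"] == "DM-cis-motif" else "structure"
            if a["attribution"] == want:
                attr_ok += 1
    n_rec = len(matched)
    metrics = {
        "n_planted": n_truth,
        "n_recovered": n_rec,
        "n_called": len(annotated),
        "recall": recall,
        "precision": (n_rec / len(annotated)) if len(annotated) else float("nan"),
        "summit_within_2nt": (summit_ok / n_rec) if n_rec else float("nan"),
        "class_accuracy": (class_ok / n_rec) if n_rec else float("nan"),
        "attribution_accuracy": (attr_ok / attr_total) if attr_total
        else float("nan"),
        "n_attribution_eval": attr_total,
    }
    confusion = (
        pd.DataFrame(rows, columns=["truth", "predicted"])
        .value_counts()
        .unstack(fill_value=0)
        if rows else pd.DataFrame()
    )
    return metrics, confusion


def gene_level_coupling(exp: simdata.SimExperiment,
                        genotype: str = "wt") -> float:
    """Pearson R between hybrid allele log2 fold changes of m6A-GI and TPM."""
    cfg = exp.config
    genes = list(exp.genomes.gene_models["gene"])
    lengths = np.array(exp.genomes.gene_models["length"], dtype=float)

    def counts(bg, fraction):
        per_rep = []
        for rep in range(cfg.replicates):
            frags = exp.fragments[SampleKey(bg, genotype, fraction, rep)]
            per_rep.append([len(frags[g]) for g in genes])
        return np.asarray(per_rep, dtype=float).mean(axis=0)

    ip_a, inp_a = counts("hybrid_a", "ip"), counts("hybrid_a", "input")
    ip_b, inp_b = counts("hybrid_b", "ip"), counts("hybrid_b", "input")
    gi_a = (ip_a / ip_a.sum()) / np.maximum(inp_a / inp_a.sum(), 1e-12)
    gi_b = (ip_b / ip_b.sum()) / np.maximum(inp_b / inp_b.sum(), 1e-12)
    tpm_a = cistrans.compute_tpm(inp_a, lengths)
    tpm_b = cistrans.compute_tpm(inp_b, lengths)
    ok = (inp_a > 0) & (inp_b > 0) & (gi_a > 0) & (gi_b > 0)
    dgi = np.log2(gi_a[ok] / gi_b[ok])
    dtpm = np.log2(tpm_a[ok] / tpm_b[ok])
    return cistrans.methylation_expression_coupling(dgi, dtpm)


def sample_indices(exp: simdata.SimExperiment, sites_by_bg: dict,
                   params: peakcall.PeakCallParams,
                   norm: dict | None = None) -> pd.DataFrame:
    """m6A sample index per background and genotype, over all detected sites."""
    cfg = exp.config
    norm = norm or _normalized_tracks(exp)
    rows = []
    genotypes = ("wt", "ko") if cfg.ko_included else ("wt",)
    for bg in BACKGROUNDS:
        sites = sites_by_bg.get(bg, [])
        if not sites:
            continue
        for gt in genotypes:
            for rep in range(cfg.replicates):
                ip = norm[SampleKey(bg, gt, "ip", rep)]
                inp = norm[SampleKey(bg, gt, "input", rep)]
                si = peakcall.sample_index(ip, inp, sites, params.score1_window)
                rows.append({"background": bg, "genotype": gt,
                             "replicate": rep, "sample_index": si})
    return pd.DataFrame(rows)


def run_full(config: RunConfig, outdir: str | None = None) -> AttributionReport:
    """Execute the whole synthetic pipeline and evaluate against truth."""
    logger.info("simulating experiment (seed=%d)", config.simulation.seed)
    exp = simdata.simulate(config.simulation)
    norm = _normalized_tracks(exp)
    logger.info("calling peaks in %d backgrounds", len(BACKGROUNDS))
    sites_by_bg = call_peaks_all_backgrounds(exp, config.peaks, norm)
    maps = build_allele_maps(exp, config.align)
    merged = merge_sites(sites_by_bg, maps)
    scored = score_sites_all_backgrounds(exp, merged, maps, config.peaks, norm)
    annotated = annotate_sites(exp, scored, maps, config)
    metrics, confusion = evaluate_against_truth(exp, annotated)
    if len(annotated) >= 3 and annotated["delta_parental"].var() > 0:
        r, ve = cistrans.cis_fraction(annotated)
        metrics["cis_R"] = r
        metrics["cis_variance_explained_pct"] = ve
    try:
        metrics["gi_tpm_coupling_R"] = gene_level_coupling(exp)
    except ValueError:
        metrics["gi_tpm_coupling_R"] = float("nan")
    class_fractions = (
        annotated["site_class"].value_counts(normalize=True).to_dict()
        if len(annotated) else {}
    )
    report = AttributionReport(
        sites=annotated.reset_index(drop=True),
        class_fractions=class_fractions,
        metrics=metrics,
        config_hash=config.config_hash(),
        confusion=confusion,
    )
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        io_mod.write_experiment(exp, os.path.join(outdir, "simulated"))
        io_mod.write_tsv(annotated, os.path.join(outdir, "comparisons.tsv"))
        if confusion is not None and len(confusion):
            confusion.to_csv(os.path.join(outdir, "confusion.tsv"), sep="\t")
        with open(os.path.join(outdir, "metrics.json"), "w") as fh:
            json.dump({"config_hash": report.config_hash,
                       "metrics": metrics,
                       "class_fractions": class_fractions}, fh, indent=2)
    return report


def benchmark_recovery(configs: list[RunConfig]) -> pd.DataFrame:
    """Recovery metrics across a grid of run configurations."""
    rows = []
    for rc in configs:
        rep = run_full(rc)
        row = {
            "seed": rc.simulation.seed,
            "ip_enrichment_max": rc.simulation.ip_enrichment_max,
            "input_depth": rc.simulation.input_depth,
            **rep.metrics,
        }
        rows.append(row)
    return pd.DataFrame(rows)
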