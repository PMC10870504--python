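# hybridm6a

Allele-resolved analysis of N6-methyladenosine (m6A) for hybrid MeRIP
experiments: near single-nucleotide peak calling from IP/input coverage,
cis/trans classification of methylation divergence between alleles,
attribution of cis changes to consensus-motif disruption or local RNA
secondary structure, reporter-oligo design for structure perturbation
assays, and m6A-QTL mechanism annotation — together with a fully specified
synthetic hybrid data generator with planted ground truth, so the entire
pipeline runs and validates itself without any external data.

## The scientific problem

m6A is the most abundant internal mRNA modification and destabilizes the
transcripts that carry it, yet its genomic distribution differs widely
between related species and between individuals.  Those differences can be
encoded in the local sequence (**cis**) or in the cellular environment —
writers, erasers, cofactors (**trans**).  An interspecies hybrid separates
the two formally: both parental alleles share one cellular environment, so
any methylation difference that persists between the two alleles *within*
the hybrid is cis-encoded, while parental differences that vanish in the
hybrid are trans-driven.

For each methylation site the package computes enrichment scores in four
backgrounds and the two contrasts

```
Δparental = log2 s(parent A) − log2 s(parent B)
Δhybrid   = log2 s(hybrid allele A) − log2 s(hybrid allele B)
```

where `s` is the site's m6A enrichment (score1, the mean IP/input coverage
ratio in an 81-nt window).  With fold-change threshold T = 1.6 log2 units,
sites are classified as **invariable** (|Δh| ≤ T, |Δp| ≤ T), **DM-cis**
(both exceed T with the same sign), **DM-trans** (|Δp| > T only), or
**cis–trans interaction** (|Δh| > T with |Δp| ≤ T or discordant sign).  The
global cis contribution is summarized by the Pearson correlation R of
Δhybrid against Δparental; 100·R² is the percent of divergence explained in
cis.

DM-cis sites are then attributed to a mechanism:

* **motif** — a substitution at positions −4, −2, −1, 0, +1 or +4 around
  the methylated adenosine (plus +2 in mammals) from the tabulated set of
  disruptive changes (consensus DRAC in yeast, DRACH in mammals);
* **structure** — intact motif, but the 61-nt windows centered on the
  homologous adenosines fold with a large minimum-free-energy difference
  (|ΔMFE| above a margin, most-structured allele below −8 kcal/mol),
  i.e. the motif is buried in a stem on the hypomethylated allele;
* **unexplained** otherwise.

## Peak calling

The caller reproduces an optimized MeRIP filtering cascade: per-position
**score2** (51-nt windowed IP coverage over the gene median), candidate
windows (>15 consecutive nt with score2 > 4), a per-replicate **winScore**
filter (IP score2 / input score2 ≥ 2 in every replicate), summit
localization on replicate-aggregated coverage, assignment of the nearest
consensus-motif adenosine, **score1** > 3 for reporting, and a
methyltransferase-KO filter (WT/KO window-score ratio > 3 plus Student
t-test p < 0.05).  Sample- and gene-level indices (m6A-SI, m6A-GI), TPM,
and a fragment-matched IDENT-score (enrichment restricted to RNA fragments
identical between alleles) support the downstream analyses.

## Worked example

```python
from hybridm6a import pipeline, simdata

config = pipeline.RunConfig(simulation=simdata.SimulationConfig(seed=11, n_genes=30))
report = pipeline.run_full(config)
m = report.metrics
print(f"planted sites: {m['n_planted']}, called: {m['n_called']}")
print(f"recall: {m['recall']:.3f}, summit within 2 nt: {m['summit_within_2nt']:.3f}")
print(f"class accuracy: {m['class_accuracy']:.3f}, "
      f"mechanism attribution: {m['attribution_accuracy']:.3f}")
print(f"parental-vs-hybrid delta R: {m['cis_R']:.3f} "
      f"({m['cis_variance_explained_pct']:.1f}% variance in cis)")
print(report.sites[["gene", "pos_a", "delta_parental", "delta_hybrid",
                    "site_class", "attribution"]].head(5).round(2).to_string(index=False))
```

prints

```
planted sites: 36, called: 36
recall: 1.000, summit within 2 nt: 1.000
class accuracy: 1.000, mechanism attribution: 1.000
parental-vs-hybrid delta R: 0.742 (55.0% variance in cis)
 gene  pos_a  delta_parental  delta_hybrid site_class attribution
g0000   1493           -2.34         -2.32     DM-cis       motif
g0001    514           -1.93          0.15   DM-trans       trans
g0001   1865           -0.13          0.25 invariable        none
g0002   1024           -0.06          2.35  cis-trans       trans
g0003    638            0.67          0.14 invariable        none
```

Each row is one called site placed on allele-A coordinates.  The first is a
cis change explained by a motif-disrupting substitution (both contrasts
agree at −2.3 log2 units); the second loses its parental difference in the
hybrid, the signature of a trans effect; the fourth shows the opposite
pattern (an allelic difference arising only in the hybrid).  The R of 0.74
reflects this mixture — on all-cis truth it rises above 0.9.

A `hybridm6a` command-line tool wraps the same stages
(`simulate`, `callpeaks`, `run`, `mpra-design`, `qtl`, `benchmark`); try
`hybridm6a run --seed 7 --out out/`.

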