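# Methods

This note documents the models, parameter choices and numerical decisions
behind `hybridm6a`, in the package's own terms.

## Enrichment scores and the peak-calling cascade

All coverage is 0-based, per-base, per gene, and library-normalized to
counts per million within each (sample, fraction, replicate) before tracks
are combined.  Both score1 and score2 are ratios of coverage from the same
track pair and are therefore invariant to uniform rescaling.

* **score2(i)** = mean IP coverage in a 51-nt window centered on `i`
  divided by the gene's median IP coverage.  Windows are truncated at gene
  boundaries (mean over available positions) rather than padded, which
  avoids edge artifacts on short genes.  A gene with zero median coverage
  is skipped with a warning.
* **Candidate windows** are maximal runs with score2 strictly above 4 at
  every position and length strictly greater than 15 nt.  Detection runs on
  the replicate-mean IP score2 profile; the subsequent winScore filter is
  per replicate.
* **winScore** = (window-mean IP score2) / (window-mean input score2),
  computed with each track's own gene median; a window is kept only if
  winScore ≥ 2 in *every* replicate.  Zero input score2 over a window makes
  the ratio +inf (kept, logged).
* **Summit** = argmax of the replicate-summed normalized IP coverage within
  the window; ties take the leftmost position.  The nearest consensus-motif
  adenosine (DRAC in yeast mode, DRACH in mammal mode; the mode is set in
  configuration, never inferred) becomes the putative site; equidistant
  candidates resolve upstream.  No maximum summit-to-motif distance is
  imposed by default — the distance is recorded and a cutoff is
  configurable.
* **score1** = mean IP / mean input coverage in an 81-nt window centered on
  the assigned adenosine, averaged over replicates (arithmetic mean;
  geometric mean available).  Reported sites require score1 > 3 (strict).
* **KO filter**: mean WT / mean KO window score > 3 in at least one
  background plus a two-sided equal-variance Student t-test p < 0.05 for
  score1 or score2.  With zero within-group variance and differing means
  the p-value is taken as 0.

The **IDENT-score** recomputes score1 after restricting both fractions to
fragments that cover the motif adenosine and overlap no variant position,
removing sequence- and structure-dependent capture differences between
alleles; it is undefined (reported missing) when no qualifying fragments
remain.

## Cis/trans classification

Scores enter the contrasts floored at 1 (`score_floor`), making
present/absent comparisons quantitative: an absent site contributes
log2(1) = 0.  The decision table with threshold T = 1.6 log2 units is

| condition | class |
|---|---|
| \|Δh\| ≤ T and \|Δp\| ≤ T | invariable |
| \|Δh\| > T and \|Δp\| > T, same sign | DM-cis |
| \|Δp\| > T and \|Δh\| ≤ T | DM-trans |
| \|Δh\| > T and (\|Δp\| ≤ T or signs differ) | cis-trans |

The boundary handling (≤ vs >) and the sign rule for the cis–trans
interaction class are this package's own completion of the class
definitions; they partition the plane, so every site receives exactly one
label, and both the threshold and the floor are configurable.

Attribution precedence for DM-cis sites is explicit and logged: a
motif-disrupting substitution always wins; otherwise the site must pass the
solid-structure filter (most-structured allele < −8 kcal/mol, strict) and
show |ΔMFE| above `attribution_margin` (default 2 kcal/mol) to be called
structural; everything else is "unexplained".  The margin guards against
calling structure on MFE differences within folding-model noise.

## Homologous-coordinate maps

Cross-allele transfer uses monotone block maps derived from affine-gap
pairwise alignment (Smith–Waterman locally, Needleman–Wunsch globally)
with match +5 / mismatch −4 and gap cost `10 + 0.5·L` — the EMBOSS-style
defaults.  The dynamic programming is delegated to
`Bio.Align.PairwiseAligner` (with the open/extend translation between the
two gap conventions handled here); an independent Gotoh-style dynamic
program in `hybridm6a.reference`, itself validated against exhaustive
alignment-path enumeration on tiny instances, serves as the oracle in the
test suite.  Positions falling in alignment gaps are unmappable and their
sites drop out of cross-allele analyses; two independently produced maps
(e.g. local vs global) can be cross-validated per position and discordant
sites excluded.

## RNA folding engines

The analysis needs only window MFEs (61-nt windows centered on the
methylated adenosine; 41/51/81 supported).  Two engines:

* **external-nearest-neighbor** — ViennaRNA (RNAfold) through its Python
  bindings, used automatically when importable.  The −8 kcal/mol
  solid-structure threshold is calibrated to this model.
* **bundled-simplified** — pair energies GC −3, AU −2, GU −1 kcal/mol,
  hairpin loops ≥ 3 nt, no lone pairs, no loop penalties, solved exactly by
  an O(n³) dynamic program over helix-anchored states and verified against
  exhaustive structure enumeration for short sequences.  When this engine is
  active the threshold can be rescaled (`bundled_threshold_factor`, default
  1.0); energies are integers in this model, so its DP and traceback use
  exact comparisons.

Windows are odd by construction; with even overhang the extra base goes
upstream.  Sequences under 10 nt are unfoldable by convention (MFE 0).
No suboptimal-ensemble quantities are computed — MFE only.

## Reporter (stem-shift) designs

Inserts are 101 nt with a 21-bp perfect stem (arms at 1-based [30,50] and
[62,82], position 30+k pairing 82−k) and an 11-nt loop [51,61]; this is the
unique geometry in which the loop centers on position 56 and the downstream
arm starts at 62.  For each site the DRACH 5-mer is rewritten with its
adenosine at every shift position 56..72, arm complementarity is enforced
deferring to motif bases, and a deterministic repair loop (preference order
A>C>G>U, partners updated in pairs) removes any spurious DRACH; sites with
irreparable designs are skipped and reported.  The point mutant replaces
the methylated A with U (DRACH→DRTCH) and nothing else.

`enforce_hairpin_mfe` additionally guarantees that the annotated hairpin is
the design's MFE structure under the bundled engine.  Because that model
has no loop penalties, bulged registers and flank helices are energetically
cheap, so enforcement rewrites non-motif arm pairs as alternating G/C and
sets flanks and loop outside the motif to adenosine: inert flanks cannot
pair, the lone-pair exclusion blocks single-U pairings, and register shifts
of an alternating stem strictly lose pairs.  The minimally mutated design
is kept whenever it already folds as annotated.

Shift-series analysis summarizes enrichment per position and reports the
Spearman correlation of the median against the paired fraction of the
motif (the fraction of its 5 bases inside the arms).  The bundled
`simulate_shift_enrichment` stand-in sets enrichment proportional to the
unpaired fraction (floor 0.5, scale 8), deterministic by default.

## The synthetic hybrid generator

The generator emulates the statistical structure the analysis assumes, with
known truth for every planted site.

**Sequences.** Uniform-random RNA genes (default 100 genes of 1500–2500 nt,
plus-strand gene models with 10% 5'UTR and 20% 3'UTR).  Gene lengths and a
default of 1 planted site per gene (Poisson, ≥300 nt apart, ≥150 nt from
edges) reflect typical yeast meiotic transcripts and observed site density;
they also keep the run inside the caller's operating regime, since score2's
gene-median normalization assumes peaks are local enrichments on a mostly
unmethylated transcript — genes carrying 3+ peaks violate that assumption
and are the main source of residual misses.  Allele B diverges by
substitutions only (default rate 0.05 per nt) outside protected spans (±8 nt
around planted adenosines, plus planted stem arms), so the ground-truth
coordinate map is the identity and the aligner can be validated against it.

**Classes.**  Default mixture: invariable 0.45, DM-cis-motif 0.30,
DM-cis-structure 0.15, DM-trans 0.05, cis-trans 0.05 — roughly 45%
conserved sites, with cis changes dominating the differential fraction and
motif disruption the leading mechanism.  Methylation levels are binary:
μ = 0.9 on methylated alleles, μ = 0 on the low allele of DM sites (a DM
site is modeled as present/absent).  DM-cis-motif sites carry one tabulated
disrupting substitution in the low allele; DM-cis-structure sites keep the
motif intact in both alleles and plant an 11-bp stem (positions +12..+22
reverse-complementary to −5..+5) in the low allele while the high allele
gets a low-pairing A/C stretch at the homologous positions; DM-trans sites
have no local variant and differ only between parents; cis-trans sites
differ only between hybrid alleles.

**Coverage.**  Sequencing is modeled at the fragment level, and coverage
tracks are the exact pileup of the emitted fragments (so fragment-derived
coverage always equals the written bedGraph).  Background fragments
(length ~ N(150, 20) nt) fall uniformly; their count is Poisson with a
gamma-distributed gene-expression multiplier (shape `nb_dispersion`,
default 20) shared between the IP and input fractions of a replicate —
both fractions are split from one RNA pool, so expression noise is common
to them and cancels in enrichment ratios.  Per-base coverage is then
marginally negative binomial with mean `input_depth × expression factor`
and size `nb_dispersion`.  IP samples get an additional per-gene,
per-replicate pulldown-efficiency multiplier (gamma, shape 50) and, per
site, enrichment fragments that all contain the methylated adenosine:
count Poisson with rate (E−1)·μ·depth (E = `ip_enrichment_max`, default 8),
spans ~ N(2·`peak_halfwidth`, 0.1·2·`peak_halfwidth`), offsets uniform.
Uniform offsets pile site-containing fragments into a triangular peak with
its apex exactly on the adenosine and summit IP/input ratio 1 + (E−1)·μ;
the realized triangle half-width equals the enrichment-fragment span
(≈150 nt at the default `peak_halfwidth` = 75).  KO genotypes set μ = 0
everywhere.

**Expression.**  Gene base factors are log-normal (σ = 0.5 natural-log
units); alleles additionally diverge by a methylation-independent cis
offset (N(0, 0.4) log2 units, maintained in the hybrid), and methylated
alleles are down-weighted by 2^(−0.5·mean site μ), modeling m6A-driven
decay.  This makes gene-level methylation changes (Δm6A-GI) anticorrelate
with expression changes (ΔTPM) in WT and leaves the KO null flat.

**Determinism.**  All randomness derives from one seed through
`SeedSequence` spawn keys per (gene, sample) counter, so adding genes or
samples never shifts other genes' draws, and fixed seeds give bit-identical
outputs including FASTA/bedGraph bytes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping ambiguity, indels
and rearrangements between alleles, splicing, non-uniform fragment-start
biases, antibody sequence preferences, clustered/overlapping peaks within
one enrichment window, and quantitative (non-binary) methylation
differences.

## QTL annotation

Proximal putatively causal variants: strict p < 0.01, distance ≤ 50 nt from
the peak center (30 nt is the reporter-selection default; both exposed),
exonic.  Mechanism annotation compares motif sets between equal-length
ref/alt windows; records that both create and destroy motifs are labeled
`complex`.  Beta follows the convention that positive values mean the
alternative allele is more methylated; beta classes are >1 / [−1, 1] / <−1.
Association between mechanism and beta sign uses Fisher's exact test on the
2×2 table.  A synthetic QTL builder with mechanism-forced beta signs
validates the machinery.

## Evaluation metrics

A planted site counts as recovered when a called site in the same gene lies
within 5 nt of the planted adenosine (sites from different backgrounds are
merged at 3 nt on allele-A coordinates).  Summit accuracy is the fraction
of recovered sites whose summit is within 2 nt of the planted adenosine.
Class accuracy compares predicted classes with truth collapsed to
invariable/DM-cis/DM-trans/cis-trans; attribution accuracy is evaluated on
recovered sites whose true class is DM-cis-motif or DM-cis-structure.  The
default simulation plants ~100 sites so these Monte-Carlo estimates have
adequate precision.

## Known limitations

* score2's gene-median normalization degrades when peaks cover most of a
  transcript (dense multi-site genes); such sites can be missed by design.
* The bundled folding model has no loop penalties, so its MFE structures
  are bulge-rich relative to the nearest-neighbor model; the −8 kcal/mol
  threshold is calibrated to the external engine.
* Classification is threshold-based, not a per-site statistical test; sites
  with true contrasts near 1.6 log2 units classify noisily.
* The cis-fraction R is computed across all called sites; mixtures with
  trans classes necessarily lower it relative to all-cis truth.
* Homology maps come from a single pairwise alignment per gene; paralogy
  and rearrangements are out of scope.
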