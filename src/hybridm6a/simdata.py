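"""Synthetic two-allele hybrid MeRIP experiment with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
pair of diverged alleles (substitution-only divergence), planted consensus
motifs with latent methylation levels mu in [0, 1], and IP/input coverage
for parental and hybrid backgrounds with and without a methyltransferase
knockout (mu = 0 everywhere in the KO).

Planted sites belong to one of five classes:

* ``invariable``        -- same mu on both alleles in every background;
* ``DM-cis-motif``      -- the low-mu allele carries a motif-disrupting
                           substitution from the disruption table;
* ``DM-cis-structure``  -- both alleles keep an intact motif, but the low-mu
                           allele carries a planted complementary stem that
                           buries the motif in a hairpin;
* ``DM-trans``          -- parental strains differ, hybrid alleles agree
                           (the divergence lives in the cellular
                           environment);
* ``cis-trans``         -- hybrid alleles differ while parents agree.

Sequencing is modeled at the fragment level.  Background fragments fall
uniformly; their count per (gene, sample, fraction, replicate) is
gamma-Poisson mixed, so per-base coverage is marginally negative binomial
with mean ``input_depth x expression factor`` and size ``nb_dispersion``.
IP samples add site-containing enrichment fragments whose uniform offsets
pile up into a triangular peak centered exactly on the methylated A, with
summit IP/input ratio 1 + (ip_enrichment_max - 1) * mu.  Coverage tracks
are the exact pileup of the emitted fragments.

All randomness flows from one seed; independent sub-streams are derived per
(gene, sample) by counter so adding genes or samples does not disturb other
draws.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import motif as motif_mod
from .peakcall import fragment_coverage

SITE_CLASSES = (
    "invariable", "DM-cis-motif", "DM-cis-structure", "DM-trans", "cis-trans",
)

DEFAULT_CLASS_MIXTURE = {
    "invariable": 0.45,
    "DM-cis-motif": 0.30,
    "DM-cis-structure": 0.15,
    "DM-trans": 0.05,
    "cis-trans": 0.05,
}

COMPLEMENT = str.maketrans("ACGU", "UGCA")

SampleKey = namedtuple("SampleKey", "background genotype fraction replicate")

BACKGROUNDS = ("parent_a", "parent_b", "hybrid_a", "hybrid_b")
#: allele carried by each background
BACKGROUND_ALLELE = {
    "parent_a": "a", "parent_b": "b", "hybrid_a": "a", "hybrid_b": "b",
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1500, 2500)
    substitution_rate: float = 0.05
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE))
    sites_per_gene: float = 1.0
    input_depth: float = 50.0
    nb_dispersion: float = 20.0
    ip_enrichment_max: float = 8.0
    peak_halfwidth: int = 75
    fragment_length: tuple[float, float] = (150.0, 20.0)
    replicates: int = 3
    ko_included: bool = True
    mode: str = "yeast"
    mu_high: float = 0.9
    mu_low: float = 0.0
    expression_sigma: float = 0.5
    #: log2 expression reduction per unit of gene methylation load
    expression_m6a_effect: float = 0.5
    #: sd (log2) of methylation-independent allele expression divergence
    allele_expression_sigma: float = 0.4
    #: gamma size of per-gene, per-replicate IP pulldown efficiency
    ip_efficiency_dispersion: float = 50.0

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        if set(self.class_mixture) - set(SITE_CLASSES):
            raise ValueError("unknown site class in mixture")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        for name in ("n_genes", "replicates", "peak_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.input_depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth and dispersion must be > 0")


@dataclass
class GenomePair:
    sequences_a: dict
    sequences_b: dict
    variants: pd.DataFrame      # gene, position, base_a, base_b
    gene_models: pd.DataFrame   # gene, length, strand, utr5_end, cds_end


@dataclass
class SimExperiment:
    config: SimulationConfig
    genomes: GenomePair
    truth: pd.DataFrame
    coverage: dict              # SampleKey -> {gene: int array}
    fragments: dict             # SampleKey -> {gene: (n, 2) int array}
    expression: pd.DataFrame    # gene x background expression factors

    def sample_keys(self):
        return list(self.coverage)


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


_SITE_MARGIN = 150
_SITE_SPACING = 300


def _plant_context(seq: list, a: int, rng) -> None:
    # extended consensus: A at -4, G at -2/-1, A-C core, H at +2, U at +4
    seq[a - 4] = "A"
    seq[a - 2] = "G"
    seq[a - 1] = "G"
    seq[a] = "A"
    seq[a + 1] = "C"
    seq[a + 2] = "ACU"[rng.integers(3)]
    seq[a + 4] = "U"


_DISRUPTION_CHOICES = [
    (-4, "A"), (-2, "G"), (-1, "G"), (1, "C"), (4, "U"),
]


def generate_genome_pair(
    config: SimulationConfig,
) -> tuple[GenomePair, pd.DataFrame]:
    """Generate allele sequences, variants, gene models and planted truth."""
    seqs_a, seqs_b = {}, {}
    models, variants, truth_rows = [], [], []
    table = motif_mod.disruption_table(config.mode)
    lo_len, hi_len = config.gene_length_range

    for gi in range(config.n_genes):
        rng = _rng(config.seed, 1, gi)
        gene = f"g{gi:04d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        seq_a = list("ACGU"[b] for b in rng.integers(0, 4, length))

        utr5_end = int(0.10 * length)
        cds_end = int(0.80 * length)
        models.append((gene, length, "+", utr5_end, cds_end))

        # choose site positions with margins and spacing
        n_sites = int(rng.poisson(config.sites_per_gene))
        span = length - 2 * _SITE_MARGIN
        positions = []
        if span > 0:
            attempts = 0
            while len(positions) < n_sites and attempts < 50:
                attempts += 1
                cand = int(rng.integers(_SITE_MARGIN, length - _SITE_MARGIN))
                if all(abs(cand - p) >= _SITE_SPACING for p in positions):
                    positions.append(cand)
        positions.sort()

        protected = set()
        site_specs = []
        classes = list(config.class_mixture)
        probs = np.array([config.class_mixture[c] for c in classes])
        for a in positions:
            _plant_context(seq_a, a, rng)
            cls = classes[rng.choice(len(classes), p=probs)]
            low = "ab"[rng.integers(2)] if cls.startswith("DM") or cls == "cis-trans" else None
            site_specs.append((a, cls, low))
            protected.update(range(a - 8, a + 9))

        seq_b = list(seq_a)

        for a, cls, low in site_specs:
            mu = {bg: config.mu_high for bg in BACKGROUNDS}
            attribution = "none"
            low_seq = seq_a if low == "a" else seq_b
            high_seq = seq_b if low == "a" else seq_a
            if cls == "DM-cis-motif":
                off, base = _DISRUPTION_CHOICES[rng.integers(len(_DISRUPTION_CHOICES))]
                choices = sorted(b for (o, f, b) in table if o == off and f == base)
                low_seq[a + off] = choices[rng.integers(len(choices))]
                mu[f"parent_{low}"] = config.mu_low
                mu[f"hybrid_{low}"] = config.mu_low
                attribution = "motif"
            elif cls == "DM-cis-structure":
                arm = "".join(low_seq[a - 5:a + 6]).translate(COMPLEMENT)[::-1]
                for k, b in enumerate(arm):
                    low_seq[a + 12 + k] = b
                # keep the high allele open at the homologous positions
                for k in range(11):
                    high_seq[a + 12 + k] = "AC"[rng.integers(2)]
                protected.update(range(a - 8, a + 23))
                mu[f"parent_{low}"] = config.mu_low
                mu[f"hybrid_{low}"] = config.mu_low
                attribution = "structure"
            elif cls == "DM-trans":
                mu[f"parent_{low}"] = config.mu_low
                attribution = "trans"
            elif cls == "cis-trans":
                mu[f"hybrid_{low}"] = config.mu_low
                attribution = "trans"
            truth_rows.append({
                "gene": gene, "a_position": a, "a_position_b": a,
                "true_class": cls, "low_allele": low or "",
                "mu_parent_a": mu["parent_a"], "mu_parent_b": mu["parent_b"],
                "mu_hybrid_a": mu["hybrid_a"], "mu_hybrid_b": mu["hybrid_b"],
                "attribution": attribution,
            })

        # background substitutions (allele B diverges) outside protected spans
        if config.substitution_rate > 0:
            hits = np.flatnonzero(
                rng.random(length) < config.substitution_rate
            )
            for p in hits:
                if int(p) in protected:
                    continue
                alt = "ACGU".replace(seq_b[p], "")
                seq_b[p] = alt[rng.integers(3)]

        sa, sb = "".join(seq_a), "".join(seq_b)
        seqs_a[gene], seqs_b[gene] = sa, sb
        for p, (x, y) in enumerate(zip(sa, sb)):
            if x != y:
                variants.append((gene, p, x, y))

    genomes = GenomePair(
        sequences_a=seqs_a,
        sequences_b=seqs_b,
        variants=pd.DataFrame(variants, columns=["gene", "position", "base_a", "base_b"]),
        gene_models=pd.DataFrame(
            models, columns=["gene", "length", "strand", "utr5_end", "cds_end"]
        ),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "a_position", "a_position_b", "true_class", "low_allele",
                 "mu_parent_a", "mu_parent_b", "mu_hybrid_a", "mu_hybrid_b",
                 "attribution"],
    )
    return genomes, truth


def _expression_factors(genomes, truth, config) -> pd.DataFrame:
    """Per-gene, per-background expression factors.

    A log-normal gene factor (sigma = expression_sigma) is shared across
    backgrounds; methylated alleles are additionally down-regulated by
    2^(-expression_m6a_effect * mean site mu), modeling m6A-driven decay.
    """
    rows = {}
    mu_by_gene = {
        bg: truth.groupby("gene")[f"mu_{bg}"].mean() for bg in BACKGROUNDS
    }
    for gi, gene in enumerate(genomes.gene_models["gene"]):
        rng = _rng(config.seed, 2, gi)
        base = float(rng.lognormal(mean=0.0, sigma=config.expression_sigma))
        # methylation-independent cis expression divergence, maintained in
        # the hybrid alleles
        allele_delta = float(rng.normal(0.0, config.allele_expression_sigma))
        row = {}
        for bg in BACKGROUNDS:
            sign = 0.5 if BACKGROUND_ALLELE[bg] == "a" else -0.5
            allele_base = base * 2.0 ** (sign * allele_delta)
            load = float(mu_by_gene[bg].get(gene, 0.0))
            row[bg] = allele_base * 2.0 ** (-config.expression_m6a_effect * load)
            row[f"{bg}_ko"] = allele_base
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _gene_fragments(rng, length, depth, sites, config, enriched, g=1.0) -> np.ndarray:
    """Fragment intervals for one (gene, sample, fraction, replicate).

    ``g`` is the replicate's gene-expression multiplier; it is shared between
    the IP and input fractions of a replicate (both are split from the same
    RNA pool), which gives per-base coverage a negative-binomial marginal
    while keeping IP/input ratios free of spurious expression noise.
    """
    mean_len, sd_len = config.fragment_length
    n_bg = rng.poisson(depth * g * (length + mean_len) / mean_len)
    lens = np.maximum(30, np.rint(rng.normal(mean_len, sd_len, n_bg)).astype(int))
    starts = rng.integers(-int(mean_len) + 1, length, n_bg)
    ends = starts + lens
    frags = [np.column_stack((np.maximum(0, starts), np.minimum(length, ends)))]
    if enriched:
        span_mean = 2.0 * config.peak_halfwidth
        for a, mu in sites:
            rate = (config.ip_enrichment_max - 1.0) * mu * depth * g
            n_e = rng.poisson(rate)
            spans = np.maximum(
                20, np.rint(rng.normal(span_mean, 0.1 * span_mean, n_e)).astype(int)
            )
            offs = (rng.random(n_e) * spans).astype(int)
            s = a - offs
            e = s + spans
            frags.append(np.column_stack((np.maximum(0, s), np.minimum(length, e))))
    out = np.concatenate(frags) if frags else np.empty((0, 2), dtype=int)
    return out[out[:, 0] < out[:, 1]]


def simulate_experiment(
    genomes: GenomePair,
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> SimExperiment:
    """Emit fragments and derived coverage for every background, genotype,
    fraction and replicate."""
    genotypes = ("wt", "ko") if config.ko_included else ("wt",)
    keys = [
        SampleKey(bg, gt, fr, rep)
        for bg in BACKGROUNDS
        for gt in genotypes
        for fr in ("ip", "input")
        for rep in range(config.replicates)
    ]
    expression = _expression_factors(genomes, truth, config)
    truth_by_gene = dict(tuple(truth.groupby("gene"))) if len(truth) else {}

    coverage = {key: {} for key in keys}
    fragments = {key: {} for key in keys}
    genes = list(genomes.gene_models["gene"])
    lengths = dict(zip(genes, genomes.gene_models["length"]))
    k = config.nb_dispersion
    for gi, gene in enumerate(genes):
        length = int(lengths[gene])
        tg = truth_by_gene.get(gene)
        # replicate-level expression multipliers, shared by the IP and input
        # fractions of a replicate (one RNA pool per culture)
        g_expr, g_ip = {}, {}
        k_ip = config.ip_efficiency_dispersion
        for bi, bg in enumerate(BACKGROUNDS):
            for ti, gt in enumerate(genotypes):
                grng = _rng(config.seed, 4, gi, bi, ti)
                for rep in range(config.replicates):
                    g_expr[(bg, gt, rep)] = grng.gamma(k) / k
                    g_ip[(bg, gt, rep)] = grng.gamma(k_ip) / k_ip
        for ki, key in enumerate(keys):
            rng = _rng(config.seed, 3, gi, ki)
            col = key.background if key.genotype == "wt" else f"{key.background}_ko"
            depth = config.input_depth * float(expression.loc[gene, col])
            sites = []
            if tg is not None and key.genotype == "wt":
                mucol = f"mu_{key.background}"
                sites = list(zip(tg["a_position"], tg[mucol]))
            g = g_expr[(key.background, key.genotype, key.replicate)]
            if key.fraction == "ip":
                g *= g_ip[(key.background, key.genotype, key.replicate)]
            frags = _gene_fragments(
                rng, length, depth, sites, config,
                enriched=(key.fraction == "ip"), g=g,
            )
            fragments[key][gene] = frags
            coverage[key][gene] = fragment_coverage(frags, length)
    return SimExperiment(
        config=config, genomes=genomes, truth=truth,
        coverage=coverage, fragments=fragments, expression=expression,
    )


def simulate(config: SimulationConfig) -> SimExperiment:
    """Convenience wrapper: genome pair + experiment in one call."""
    genomes, truth = generate_genome_pair(config)
    return simulate_experiment(genomes, truth, config)


def ko_config(config: SimulationConfig) -> SimulationConfig:
    """A copy of the configuration with methylation abolished everywhere
    (all classes invariable at mu = 0): the writer-KO null condition."""
    cfg = replace(config, mu_high=0.0, mu_low=0.0,
                  class_mixture={"invariable": 1.0})
    return cfg
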