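# Methods

`cisnet` predicts genes whose cis-regulatory (TFBS) or loss-of-function
mutations are associated with trans-dysregulation of their gene networks in
a cancer cohort. This note documents the model, its parameters, the
numerical choices, what the synthetic cohorts emulate, and the limits of
what the tests demonstrate.

## The hierarchical dysregulation model

For each mutated gene *g* the model couples three levels of latent
variables:

- **Cohort level.** `D ~ Bernoulli(pi_d)` — *g*'s mutations are functional
  across the cohort.
- **Sample level.** For each sample *s* carrying a mutation in *g*,
  `F_s | D ~ Bernoulli(pi_f if D else eps)` — the mutation in *s* is
  functional.
- **Partner level.** For each network partner *p* of *g* (edge weight
  `w ∈ (0,1]`) and each mutated sample, a regulatory status
  `R ∈ {down, neutral, up}`. Given a functional mutation,
  `P(R ≠ neutral | F=1) = alpha·w`, split equally between up and down.
  Given no functional mutation, `R` follows the partner's **cohort-marginal
  status distribution** — the mixing weights of its fitted expression
  mixture, with each tail floored at `b/2` and renormalized.

The observed expression `y_{p,s}` enters through the partner's
three-component Gaussian mixture: the observation term for status *r* is
the status posterior divided by its mixing weight, `q_r(y)/λ_r`, i.e. the
component density relative to the cohort-marginal density. Two properties
follow:

1. **Exact null calibration.** Under `F=0` the predicted observation
   distribution *is* the cohort marginal, so the per-observation evidence
   integrates to exactly 1 and a gene whose partners merely look like the
   rest of the cohort accumulates no support. A fixed background
   probability in place of the marginal (an alternative we evaluated)
   makes every gene — and every shuffled control — look functional
   whenever the fitted tail weights exceed it, saturating all posteriors.
2. **Bounded single-observation evidence.** One observation can contribute
   at most `log(alpha·w/2 / λ_tail)` nats, so no single outlier partner
   can decide a gene.

The model is a tree, so inference is exact: statuses are summed per
observation, `F_s` per sample, then `D`, all in log space (no sampling, no
underflow at hundreds of partners). Reported posteriors:

- **GRS** — `P(R ≠ neutral)` for a partner in a sample, from the marginal
  mixture posterior (independent of `F`), signed negative when
  down-regulation dominates;
- **SSD** — `P(F_s = 1 | data)` for each mutated sample;
- **DAC** — `P(D = 1 | data)` for the gene.

Defaults: `pi_d = 0.5`, `pi_f = 0.8`, `eps = 0.01`, `alpha = 0.9`,
`b = 0.1` (all configurable via `XseqPriors`). `pi_d = 0.5` makes DAC an
even-prior Bayes factor readout; `eps` small keeps isolated passenger-like
samples from diluting a real driver; `alpha < 1` acknowledges that not
every partner responds even to a functional mutation.

Copy-number handling: a partner observation with `|GISTIC| ≥ 1` in a
sample is excluded from that sample's product — an expression shift
explained by the partner's own copy number is not usable as trans
evidence.

## Per-gene expression mixtures

Each partner's expression across samples is decomposed into
down/neutral/up components by EM. The mixture is **homoscedastic** (one
shared variance): with free variances a tail component either collapses
onto a few points or inflates to absorb half of a unimodal bulk, and a
small minority of genuinely shifted samples (e.g. 8 of 60 at 2 sd) stops
being resolvable as a low-weight tail. With a shared variance the same EM
recovers both regimes: a well-separated trimodal distribution (means
recovered within 0.05, >99% label accuracy at n=3000) and a
bulk-plus-minority-shift distribution (tail weight ≈ the minority
fraction).

Numerics: deterministic initialization at the 10th/50th/90th percentiles
with equal weights; convergence at 1e-8 log-likelihood, max 500
iterations; shared sd floored at 1e-3 of the overall sd; components
relabeled to enforce `μ_down < μ_neutral < μ_up`. Data whose spread is
below 0.01% of its magnitude bypasses EM and is declared neutral-dominant
(λ_neutral = 0.99) — EM on pure jitter would otherwise carve noise into
statuses.

## Preprocessing

- Genes with zero counts in strictly more than half the samples are
  removed; remaining counts become `log2(cpm + 1)` (pseudo-count 1;
  per-sample cpm sums to 1e6). Pre-normalized (microarray-style) matrices
  bypass both steps via a flag.
- Per-gene z-values use the cohort mean and sample (n−1) sd of the
  normalized matrix; "potentially dysregulated" means strictly `|z| > 1`.
  z-values are computed on the log2 scale — the matrix every other stage
  consumes.
- The expressed-gene filter takes each gene's 90th-percentile expression,
  splits the distribution of those values into low/high Gaussians by EM
  (deterministic 2-means initialization from the extremes; a median-split
  start can cut through the high mode when the low class is small), and
  keeps genes with posterior ≥ 0.8 for the high component.
- ASCAT allele counts convert to the 5-level GISTIC code by total copy
  number: 0 → −2, 1 → −1, 2 → 0, 3 → +1, >3 → +2.

## Mutation channels

Three channels are analyzed independently and never merged:

- **lof** — exonic mutations whose consequence is in the 11-term
  loss-of-function whitelist (nonsense, frameshift, splice-site classes;
  case/underscore-insensitive).
- **cis_protein_coding** — mutations intersecting TFBSs assigned to
  protein-coding genes, kept only in samples where the gene itself is
  potentially dysregulated (`|z| > 1`).
- **cis_mirna** — mutations in TFBSs assigned to miRNA genes; all kept (no
  z prefilter), expanded to both mature arms (5p/3p), each arm scored
  against its own target network.

TFBS→gene assignment: overlap with an annotated regulatory element wins
(all of the element's genes, since element maps are multi-valued);
otherwise the single closest TSS, protein-coding and miRNA TSSs pooled,
distance measured from the nearer interval end, ties broken by lower TSS
coordinate then gene id.

## Networks

Protein-coding gene networks are consumed as weighted edge lists; miRNA
target networks are built from predicted target records, dropping targets
with fewer than two predicted sites and weighting edges by the
context-score percentile / 100. Before inference, weights are updated
against the cohort: for each mutated source gene, partners differentially
expressed between mutated and non-mutated samples (two-sided Wilcoxon
rank-sum, BH-adjusted within the gene's partner set, α = 0.05) get weight
1 and the remaining partners are dropped; if none is significant the
original edges pass through. A flag switches to global BH adjustment. The
per-gene scope is the default because the DE question is asked per mutated
gene; a sensitivity flag exists precisely because the alternative is
defensible.

## Empirical FDR and selection

100 controls are generated by (i) shuffling the updated network —
per-source degrees kept, partner slots refilled uniformly without
replacement, the global weight multiset permuted — and (ii) permuting the
gene labels of the mutation matrix (per-sample burdens preserved).
Expression is never shuffled, so the per-partner mixtures are fitted once
and shared across all 101 runs. The DAC threshold *t* is the smallest
value in the pooled grid of observed and control DACs with

    FDR(t) = mean_controls #{null DAC > t} / #{observed DAC ≥ t} ≤ 0.05,

floored at 0.5 (null exceedance is strict so a cutoff sitting exactly on
the top null value excludes it). Selected genes need `DAC ≥ t` and
`SSD ≥ 0.5` in at least two samples. Dysregulation tables list partners
with `|GRS| ≥ 0.5` in ≥ 1 sample with `SSD ≥ 0.5`, down-regulation
negated. Control seeds derive from the master seed by a counter, so runs
are reproducible and order-independent.

## Mutation-rate analysis

Per sample, the rate in a region set is (distinct mutated reference
positions inside the set) / (set length); an indel contributes its
overlapping span. Region sets: merged TFBSs, merged exons, and their
100/500/1000-nt flanks with TFBS and exonic bases subtracted (flanks per
width are full flanks, not annuli). Expectations come from 150
chromosome-preserving uniform re-placements (reference-span preserved so
indels stay on-chromosome); the cohort comparison is a paired two-tailed
Wilcoxon signed-rank of per-sample TFBS vs exon rates — paired because the
two rates are measured on the same samples.

## Synthetic cohorts

The generator emulates the input trios (mutations, RNA-seq, small-RNA) of
a tumor cohort at desk scale. Defaults: 2 chromosomes × 1 Mb, 200
protein-coding genes and 20 pri-miRNAs on evenly spaced loci, 1000 TFBSs
within 2 kb upstream of TSSs (half covered by element records), 60
samples. Baseline counts are negative-binomial (gamma–Poisson) with
log-normal gene means, dispersion 0.2, log-normal library factors, and a
15% lowly-expressed gene class so the zero filter and expressed-gene
filter both have real work to do. Five planted drivers each carry one
TFBS mutation in 8 designated samples; in those samples the driver's own
expression shifts in cis by ±Δ·sd (the z prefilter presumes exactly this)
and 70% of its partners shift in trans by ±Δ·sd each with a fixed
per-partner direction (Δ = 2 by default, half up / half down). One planted
pri-miRNA driver shifts the targets of its 5p arm. Effects are applied by
scaling counts by `2^(±Δ·sd)` and rounding — ground-truth effect sizes are
exact up to integer rounding (<1% at the default count scale). Background
mutations are uniform at 1e-5 /nt/sample; exonic ones draw consequence
terms (10% nonsense, 10% frameshift). CNA entries are ±1/±2 at rate 0.02;
survival is exponential with log-hazard linear (slope 0.8) in one
designated miRNA's expression, ~30% censoring. `null_mode` switches off
every planted effect and the hazard link without touching the marginal
distributions. One master seed makes every emitted file byte-identical.

What the generator does **not** emulate: mutational signatures and
trinucleotide context, structural variants, linked CNA–expression dosage,
subclonality, batch effects, and correlated gene–gene baseline expression.
Passing the recovery and calibration tests therefore shows the machinery
is correct and calibrated under the stated generative model — not that
real-cohort sensitivity matches these numbers.

## Problem sizes used in the shipped checks

The automated checks run the full pipeline (100 shuffled controls per
run) on the default 60×200 cohorts: driver recovery over 10 seeds, null
calibration over 20 seeds, plus exact-oracle comparisons (per-base
interval arithmetic, brute-force enumeration of the hierarchical model,
exact hypergeometric summation, a permutation log-rank oracle) at small
n. These sizes keep a complete run in minutes on one CPU while every
stage — including the empirical FDR — executes for real.

## Known limitations

- Directional consistency of a partner across samples is not modeled
  (up and down are pooled symmetrically into "non-neutral").
- The priors are fixed, not learned by empirical Bayes; `alpha·w` is one
  consistent parameterization of weighted partner influence.
- The cis-analysis mode of the original framework (mutation → own-gene
  expression) is out of scope; the z prefilter is the only cis coupling.
- Pathway-database enrichment is export-only: the package computes
  hypergeometric enrichment against user-supplied gene sets and writes
  gene lists for external tools.
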