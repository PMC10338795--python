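# Methods

This note documents the models, numerical choices and simulation designs
behind sarcoscreen, and what the synthetic benchmarks do and do not show
about real data.

## Screen normalization and hit calling

Relative viability is the ratio of a drug well's luminescence to the
arithmetic mean of the plate's DMSO control wells. The mean (rather than the
median) is used because it is the linear unbiased aggregate under the
multiplicative-noise model below; the aggregation is exposed as an option
(`control_agg="median"`) for plates with control outliers. Viabilities above
1 (apparent stimulation) are retained rather than clipped so that QC can see
them. Normalization is per plate; with several cell lines, each line's plate
is normalized independently and hit calling operates on the pooled long
table.

A hit requires inhibition **strictly greater** than the threshold (default
0.60) in at least one cell line. All threshold comparisons in the package
follow the printed symbol: ">" and "<" are strict, "≥" and "≤" inclusive.

## Four-parameter logistic dose-response

The 4PL curve v(d) = bottom + (top − bottom)/(1 + (d/IC50)^h) is fitted in
log-dose space, where the model is a logistic in log d and the optimization
landscape is better conditioned. Bounded trust-region least squares
(`scipy.optimize.least_squares`) is run from 10 starts (five midpoint
quantiles of the observed log-dose range × two Hill-slope guesses, 1 and 2);
top/bottom are bounded to [−0.1, 1.5] and the midpoint to the observed dose
range ± half a decade. The best-SSE solution is kept, re-oriented so that
top ≥ bottom with a positive slope, and `converged` requires optimizer
success plus a positive slope. Flat data (all viabilities equal) returns
`converged=False` with an undefined IC50 rather than an arbitrary midpoint.
IC50 is reported as the fitted midpoint parameter — the dose of
half-maximal *fitted* effect, not the dose where v = 0.5 when the plateaus
differ from 1 and 0.

Combination doses are selected on a half-log grid spanning the fitted dose
range: the largest grid dose whose predicted inhibition is strictly below
0.5. A grid (rather than analytic inversion) matches how combination plates
are actually dosed.

## Synergy models

Fractional responses are **inhibitions** (1 − viability); Bliss independence
applies to effect probabilities, and inhibition is the effect here. The
Bliss expectation is Pt = Pa + Pb − Pa·Pb and the index BI = Po/Pt, undefined
when both single agents are inert (Pt = 0). The additive band around BI = 1
uses a floating-point tolerance of 1e−9; the synergistic/antagonistic
trichotomy assumes exact arithmetic otherwise. "Obvious" synergy is BI
strictly above 1.3. Replicate combination measurements are averaged before
scoring (per-replicate BIs are available from the long-form records).

For the Chou–Talalay index CI = DA/da + DB/db, the combination doses DA/DB
reaching the IC50-equivalent effect are found by log-linear interpolation of
the fixed-ratio combination's effect series between the bracketing doses
(`interpolate_effect_dose`); no parametric form is assumed for the
combination curve.

## Consensus hub genes

The ten centrality measures follow the CytoHubba conventions, with three
choices made explicit because they are potential divergence points from
other implementations:

1. **Closeness** is harmonic (sum of reciprocal distances), which is
   well-defined on disconnected graphs.
2. **BottleNeck** trees are made deterministic by visiting neighbors in
   ascending label order; a node scores one point per root whose BFS tree
   gives it a subtree (including itself) of more than n/4 nodes, with n the
   graph order.
3. **EPC** is a seeded Monte-Carlo: each edge is kept independently with
   probability 0.5 over (default) 1000 realizations and a node's score is
   its mean component size. With keep-probability 1 this equals component
   size exactly, which anchors the estimator.

Radiality uses the diameter of the node's own component and an (n − 1)
denominator over the whole graph; EcCentricity is the reciprocal graph
eccentricity, 0 for isolated nodes; MCC sums (|C| − 1)! over maximal cliques
of size ≥ 2 containing the node (Bron–Kerbosch enumeration via networkx —
acceptable because TSG-scale PPI networks are at most a few thousand nodes).

Top-k per method uses ceil(fraction × n) with ties broken by ascending node
label, guaranteeing non-empty sets on small graphs; the consensus is the
intersection of the ten top sets. The top fraction is interpreted as a
fraction of network nodes.

## Differential expression and the filter cascade

The DE engine is deliberately simple and fully specified: CPM normalization,
log2 fold change log2((mean tumor CPM + 1)/(mean normal CPM + 1)) with a
pseudocount of 1 CPM to avoid infinite ratios at zero counts, a two-sided
Wilcoxon rank-sum test (signed-rank on per-pair differences for paired
designs) on log2(CPM + 1), and Benjamini–Hochberg adjustment across all
tested genes. The cascade consumes only (log2FC, adjusted p, mean CPM), so
results from heavier engines can be fed in through the same record schema.

Filter boundaries: fold change ≥ 2 inclusive on the linear scale
(|log2FC| ≥ 1), adjusted p < 0.05 strict; the surface-target screen uses
|FC| ≥ 4 and mean tumor CPM ≥ 90, both inclusive; the single-cell filter
requires the percent of expressing cells (count > 0) to strictly exceed 25%
in at least one cell type, with "broad" meaning ≥ 5 qualifying types. Genes
missing from the pan-cancer reference are retained but flagged as
unevaluated: exclusion requires positive evidence of up-regulation
elsewhere.

## Alternative splicing

Two transcripts of a gene are aligned by exact exon matching; each maximal
run of unmatched exons (a "bubble") is classified:

* **ES** — exons on one side only, between two shared flanking exons;
* **A3SS / A5SS** — a single overlapping exon pair sharing one boundary; the
  label depends on which boundary shifts and on strand (a genomic-start
  shift is A3SS on "+", A5SS on "−");
* **IR** — a single exon on one side exactly spanning a consecutive exon
  pair on the other;
* **MEE** — one non-overlapping exon on each side between shared flanks.

Bubbles matching none of these are reported as "complex" and excluded from
the five-type counts. Classification is symmetric in transcript order and
equivariant under coordinate translation; strand reversal swaps A3SS and
A5SS and fixes the other types. GTF input is 1-based inclusive, stored
0-based half-open, and written back 1-based.

PSI uses junction counts with per-form junction normalization: an ES
inclusion form has two supporting junctions and its exclusion form one, so
psi = (inc/2)/(inc/2 + exc/1) for ES. This differs from tools that count
exon-body reads; it was chosen because it is standard, exactly testable, and
consistent under the binomial read model the generator uses. PSI is reported
missing below a total coverage floor of 10 reads — a variance control for
the SD-based heterogeneity screen; the floor is a package choice, not an
upstream convention.

The differential screen takes mean per-pair ΔPSI with a two-sided paired
t-test on the raw PSI differences (not logits, since the thresholds live on
the PSI scale), BH adjustment across events, and significance at
|ΔPSI| > 0.10 and adjusted p < 0.01, both strict. Zero-variance difference
vectors get p = 1 when the mean difference is 0 and p = 0 otherwise. The
heterogeneity screen flags events with sample SD (n − 1 denominator) of
tumor PSI strictly above 0.15, requiring ≥ 3 non-missing values.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; identical calls are byte-identical.

* **Plates / dose-response**: multiplicative lognormal noise with a stated
  CV (unit mean: σ² = log(1 + CV²), μ = −σ²/2), because plate readers show
  multiplicative error. Default screen noise CV 5%; dose-response benchmarks
  use 3%, combination screens 2%.
* **Combinations**: single-agent inhibitions come noise-free from the 4PL
  truths; the observed combined response is the Bliss expectation plus a
  planted excess, clamped to [0, 1], times noise. With zero excess and zero
  noise, BI = 1 exactly for every pair.
* **PPI networks**: G(n, p) background with mean degree 4 (typical of
  filtered PPI subnetworks), plus a planted module whose members form a
  clique and each attach to 5× the background mean degree of random nodes.
* **Expression counts**: negative binomial with var = μ + αμ² (default
  α = 0.05, a within-condition RNA-seq dispersion), lognormal baseline means
  (median 150), exactly round(de_fraction × n_genes) DE genes alternating
  up/down by 2^±lfc, and library-size factors within 2× of each other.
  The default 13 + 13 design matches a paired tumor/normal cohort.
* **Splicing**: per-sample totals ~ Poisson(coverage); inclusion reads
  binomial with probability ψ·J_inc/(ψ·J_inc + (1 − ψ)·J_exc), so the
  junction-normalized PSI estimator is consistent. Tumor PSI per patient is
  Normal(ψ_tumor, sd) truncated to [0, 1] — a simple heterogeneity model
  matched to an SD-threshold screen. Each event also emits a two-transcript
  GTF gene model realizing its type.

What the generators do **not** emulate: plate spatial (edge) effects,
batch effects and gene–gene correlation in counts, overdispersed or
multimodal patient PSI, network degree-correlation structure, or mapping
ambiguity in junction counts. Benchmarks passing on these simulations show
the estimators and filters are correct and well-calibrated under their
stated assumptions — not that those assumptions hold in any particular
dataset.

## Benchmark problem sizes

The packaged studies use: 20 seeds × 105 pairs for synergy recovery; 20
seeds × 200-node networks (8 planted hubs, EPC at 500 realizations) for hub
recovery; 25 seeds × 2000 genes × 13/13 samples each for DE power and for
type-I control; 25 seeds × 20 events (plus 10 seeds × 500 null events) at 13
pairs and coverage 100 for splicing; 100 noisy fits for IC50 recovery. These
sizes give stable estimates of the rates reported by
`scripts/acceptance.py` while keeping a full run around half a minute.

## Known limitations

* The ten centrality definitions follow published conventions but other
  implementations differ in EPC's retention model and BottleNeck's tree
  construction; rankings on real networks may differ in detail.
* The Wilcoxon-based DE test is less powerful than negative-binomial
  likelihood methods at small n and does not model dispersion trends.
* The AS classifier requires exact anchor-exon matches; annotation jitter
  at exon boundaries will push events into the "complex" category.
* CI interpolation assumes a locally monotone combination effect series.
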