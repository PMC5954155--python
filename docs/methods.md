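# Methods

## The measured quantity

A pooled CRISPRi screen competes a guide library over ~17 generations of
growth; the fitness effect of guide g is the log2 fold change of its read
share between the start and end samples. Fold changes are computed per
replicate from median-of-ratios–normalized counts with pseudocount 1
(guides that vanish from the end sample are the signal of interest and must
not produce infinities), anchored by subtracting the same quantity for a
non-targeting control guide, and averaged over replicates. Guides with
fewer than 20 reads summed over all samples are discarded. This is a
deliberately simplified point estimator: no per-guide dispersion shrinkage
or Wald testing is performed, because every downstream analysis consumes
the point log2FC only.

Two properties of this estimator matter for interpretation:

* **Composition bias is absorbed by the control anchor.** In a depletion
  screen the end-sample composition shifts toward neutral guides;
  median-of-ratios factors computed jointly over all samples leave a
  residual common offset on all log2FCs, which the control-guide
  subtraction removes.
* **The anchor carries counting noise.** Anchoring to a single guide means
  every log2FC inherits that guide's measurement noise — with negative
  binomial dispersion α and R replicates, roughly
  sqrt(2α)/ln2/sqrt(R) ≈ 0.27 at α = 0.05, R = 3. This is a property of
  the experimental design, not of the estimator; between-screen
  comparisons of absolute log2FC levels should expect a per-screen offset
  of this size.

## Positional segmentation and the neutral-region set

A CART regression tree (variance-reduction splits; scikit-learn's
`DecisionTreeRegressor`) predicts log2FC from the PAM coordinate, fitted
separately per orientation class (coding / template / promoter /
intergenic). Stratifying by orientation rather than passing it as a second
feature yields one clean genomic segmentation per class; the alternative
(joint fit) differs only in how the first split is spent. Defaults
`min_leaf = 10` guides and `max_depth = 14`: leaves should resolve
single-gene intervals (~1 kb at the library's guide density) without
chasing individual guides. Leaves predicting log2FC ≤ −3.5 — the
strong-defect threshold used throughout — are the important regions;
guides in all other leaves form the neutral-region set used for sequence
modelling and seed statistics. Multi-mapping guides (spacer+PAM found at
more than one genomic site) are excluded from positional analyses, since
their position is undefined, but kept for seed statistics.

The reverse-polar test asks whether coding-strand guides just past the
stop codon of an essential/fitness gene (that is not followed by another
important gene) are depleted: a one-sample t-test of the (0,100] nt and
(100,200] nt windows against the mean of template-strand guides in gene
bodies. The test is two-sided with the direction reported separately,
because the comparison population itself is depressed by seed-driven
toxicity and a one-sided framing would hide reversals. Windows with fewer
than 3 guides report p = NaN; a sample with zero variance reports t = 0,
p = 1 when it equals the reference and p = 0 otherwise.

## The sequence-to-fitness model

The regressor maps the one-hot spacer (or a longer window) to log2FC
through hidden layers of 40, 20, 10 and 5 tanh units. Unit i of a layer
with N units reads only previous-layer units floor(i·N_prev/N) + {−2..2},
clipped at the boundaries; the input is flattened position-major so
"proximal" respects sequence order at every depth. The proportional anchor
preserves locality as widths shrink: the receptive field of a deep unit is
a contiguous sequence window. The scalar read-out is dense over the final
5 units (a width-5 local rule there would see only units 0–2). The
parameter count (≤ 5 weights per hidden unit) is an order of magnitude
below the dense equivalent and is asserted structurally in the tests.

Training: Adam on mean squared error with L2 penalty λ on the masked
weights. Early stopping follows the validation-loss rule — stop when the
loss has not improved for more than 2 consecutive epochs — with two
implementation guards: a 20-epoch burn-in before the rule engages
(otherwise the initial optimization plateau triggers it spuriously), and
restoration of the best-epoch weights at stop. Defaults λ = 1e-4,
learning rate 1e-2, batch 64, max 300 epochs were chosen for stable
convergence of this implementation across data and initialization seeds;
all are exposed in the estimator's parameters and recorded in the saved
model artifact.

Data for the model are the neutral-region guides: by construction their
fitness carries no positional signal, so whatever the model explains is
sequence-driven. The 80/10/10 split is stratified by the 5 PAM-proximal
bases (proportional allocation within each seed group, small groups
falling to the training set, with a top-up step so validation and test are
never empty). Note what this split measures: seed groups are represented
in both training and test, so the test Pearson quantifies how well the
model predicts fitness for *new guides carrying seen seeds* — the relevant
question for library design — not generalization to unseen seeds, which
for a memorization-like effect is not identifiable.

## Mutation attribution

Single-mutation scan: for a set of random uniform ACGT sequences (default
1000), every position is set to each alternative base and the prediction
shift recorded; the per-position standard deviation over the 3·n shifts
(self-mutations excluded; they are identically zero) measures the model's
reliance on that position. Pairwise scan (default 100 sequences): for each
position pair, the 9 double-mutant effects E_ij are compared with the
summed singles E_i + E_j by Euclidean distance on the 9-vector, averaged
over sequences (averaging after pair aggregation would weight sequences
unevenly; mean-over-sequences is used). A model additive in the one-hot
encoding satisfies E_ij = E_i + E_j exactly, so the matrix is zero to
machine precision — the analytic null that the test suite asserts. The
alternative scalar statistic mean|E_ij − E_i − E_j| is available via
`mode="scalar"` and recorded in output metadata.

## Bad-seed statistics

Guides are grouped by seed5 (the 5 PAM-proximal spacer bases). Each
group's mean log2FC is tested one-sided (lower) against the reference
mean — the template-strand-of-genes guide population, which carries no
on-target signal — with Bonferroni correction over all 4^5 = 1024 seeds,
calling a seed bad at corrected p < 0.01. One-sided because the claim
under test is *reduced* fitness; a two-sided variant is a flag away. The
reference population is itself contaminated by bad-seed and off-target
guides (as it is in any real screen); this biases the reference mean
downward and makes the calls conservative. Groups with n < 3 are reported
but labelled `insufficient`. Cross-strain comparison: OLS of per-seed
means in the low-dCas9 strain on the high-dCas9 strain over seeds with
n ≥ 3 in both.

## Seed-match off-target detection

All NGG sites are indexed by their k PAM-proximal protospacer bases; a
guide's candidates are looked up exactly and extended base-by-base outward
from the PAM to the maximal identity run (no gaps; the guide's own site is
excluded; the PAM is always required). A hit matters when it falls in an
important region, defined with the repression geometry: gene bodies count
only for sense-strand (coding-orientation) hits, and only where blocking
elongation silences an essential/fitness gene directly or through the
operon; promoters of such operons count in both orientations. An
orientation-blind variant is provided for comparison. The detection-rate
curve reports, per k in 6..15, the fraction of strong-defect and
no-defect template-strand-of-neutral-gene guides with at least one
important hit at identity ≥ k; the difference curve estimates the fraction
of defects explained by off-targets and peaks at the minimal identity that
silences. A Fisher exact test on the defect × hit table accompanies it.

## The synthetic screen generator

The generator emulates the data-generating process the analyses assume,
with every per-guide effect decomposed in a truth ledger
(`effect_total = on_target + polar + offtarget + badseed`, all on the
end-vs-start log2FC scale — the screen's measured aggregate, not
per-generation fitness, which keeps the count model analytic).

Genome and annotation: operons of 1–3 genes (sizes 0.4/0.35/0.25), gene
lengths 700–1200 nt, 100-nt promoters, intergenic gaps 250–450 nt, on a
50 kb sequence; 30% of genes essential, 10% fitness. Gene knockdown
effects: essential −|N(8.0, 0.7)|, fitness −|N(5.0, 1.0)| log2FC. The
fitness-gene magnitude follows from growth-rate compounding: over ~17
generations even a 15% growth deficit is 17·log2(0.85) ≈ −4.0, so genes
with measurable growth phenotypes fall below the −3.5 strong-defect
threshold and inside the tree's important regions — which is also the
regime in which "neutral regions" are genuinely neutral.

Planted effects:

* **Bad seeds** — 20 5-mers with toxicity τ ~ −|N(4, 1)| clipped at −3,
  each stamped (seed + CGG) at ≥ 45 intergenic positions (clear of
  reverse-polar windows), so each has enough carriers for per-seed
  statistics. The effect scales linearly with the strain's dCas9 level:
  the dose response f(x) = x is the simplest monotone choice with
  f(0) = 0, f(1) = 1, and is configurable.
* **Off-target pairs** — 100 host guides on the template strand of neutral
  genes, each with its 9 PAM-proximal bases + NGG stamped into an
  essential-gene body on the sense strand (the 10th base forced to
  mismatch, so the planted identity is exactly 9 nt). The off-target
  effect is 0.65× the implicated gene-block effect — seed-only binding
  silences partially, consistent with an observed ~3-fold (rather than
  ~100-fold) repression through a 9-nt match — and scales with
  dcas9_level^0.5, a weaker dose dependence than the bad-seed effect's
  linear one, reflecting that reduced dCas9 limits off-targeting less than
  it alleviates seed toxicity.
* **Polar effects** — blocking a gene silences it and all downstream
  operon members; the aggregate effect is the strongest among the silenced
  genes. The weak reverse-polar effect adds −0.5 to coding-strand guides
  within 100 nt past a terminal important gene's stop, and nothing at
  100–200 nt.

Counts: one shared Dirichlet(1) start-abundance vector (the control guide
planted at the typical share 1/n — a normalization anchor must be a
well-represented library member); end abundance ∝ start · 2^effect;
negative binomial counts (dispersion 0.05, ~500 reads/guide — desk-scaled
from the tens of millions of reads of a real screen) drawn independently
per replicate and timepoint.

Two desk-scale departures from a plain uniform-random genome are
deliberate: planted motifs (above), and extra GG dinucleotides stamped at
random unreserved positions until the genome carries enough NGG sites with
full 20-nt flanks for the requested 8,000-guide library (a uniform 50 kb
sequence yields only ~6,250). The planted off-target count (100) is chosen
so the detection-rate curve's argmax is estimable: the positive set is
~115 guides, giving ~1% rate granularity against an expected 9-vs-8
margin of ~1.5%.

### What the generator does not model

No PCR bias, jackpot effects, or bottlenecks; no read-level errors or
FASTQ emission; no gradation of repression efficiency along the gene; no
partial-match (< full identity) on-target binding energetics; operons
never overlap and genes never wrap the origin. Consequently, passing the
recovery tests shows the analysis chain is correct and well-powered under
the assumed noise model — it does not certify performance on real screens,
where library bottlenecks and guide-specific efficiency add variance the
generator omits.

## Numerical and design choices

* Coordinates are 0-based half-open on the forward strand; the PAM
  position is the first base of NGG read on its own strand. "Coding"
  orientation = protospacer on the gene's sense strand; the convention is
  applied identically in the simulator and every analysis, so labels are
  self-consistent end to end.
* Degenerate inputs: zero-variance t-test samples report t = 0/±inf by the
  mean comparison; zero-variance model predictions report Pearson r = NaN
  with a valid RMSE; singleton seed groups report std = NaN and are
  excluded from testing with a reason.
* Determinism: every stochastic stage funnels through one
  `numpy.random.default_rng` seed; reruns with the same seed are
  bit-identical, and the CLI stamps every artifact with a config hash that
  `report` verifies.
* The scaled-down problem sizes used by the test suite and the acceptance
  script (50 kb genome, 8,000 guides, 500 reads/guide) are the package's
  default study conditions; they were chosen so each planted effect class
  is recoverable with comfortable statistical power at interactive run
  times.

## Known limitations

* The test Pearson of the sequence model varies by ~±0.1 across
  initialization seeds; the early-stopping rule occasionally halts in a
  slower optimization basin. The burn-in mitigates but does not eliminate
  this.
* The cross-strain slope on simulations sits slightly above the bad-seed
  dose ratio (≈ 0.46 vs 0.40 at levels 1.0/0.4) because level-independent
  contamination of seed groups (off-target guides at the weaker dose
  exponent, reverse-polar effects, boundary leakage of the segmentation)
  adds points above the bad-seed line. At a real screen's group sizes
  (~35 guides/seed) the same contamination is an order of magnitude
  smaller.
* With a 1024-way Bonferroni correction and group sizes around 5, only
  strong seed effects (|τ| ≳ 1.5 at the default noise) are detectable for
  unplanted seeds; the recovery numbers apply to the planted τ ≤ −3
  regime.
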