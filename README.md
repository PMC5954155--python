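# crispri-screen

Analysis pipeline for genome-wide CRISPRi (dCas9) fitness screens in
bacteria, built around the phenomenology of pooled dCas9 knockdown screens
in *E. coli*: strand-dependent silencing, operon polar effects, sequence
(seed)-driven guide toxicity, and seed-match off-target activity. It is
aimed at people analysing pooled guide-RNA count data — or designing guide
libraries — who need to separate *on-target* fitness signal from the two
artefact classes that dominate unexpected guide depletion.

## What it computes

In a pooled screen, each guide g's effect is measured as the log2 fold
change of its read abundance over a growth competition,

    log2FC_g = mean_r [ log2((end_{g,r}/s_end + p) / (start_{g,r}/s_start + p))
                        − (same term for a non-targeting control guide) ]

with median-of-ratios size factors s, pseudocount p = 1, replicates r, and
guides under 20 total reads discarded. On top of that table the pipeline
provides:

* **Positional analysis** — a CART regression tree on (PAM position,
  target orientation) segments the genome into regions of consistent
  fitness effect; leaves predicting log2FC ≤ −3.5 are "important regions"
  (essential/fitness genes and their promoters), the rest define the
  neutral-region guide set. Rolling averages and a one-sample t-test for
  the weak reverse-polar effect ≤ 100 nt past essential gene stops are
  included.
* **Sequence model** — a sparsely connected network (hidden layers
  40/20/10/5, each unit wired to the 5 proximal units of the layer below,
  tanh activations, dense scalar read-out) regresses log2FC on the one-hot
  spacer sequence of neutral-region guides; trained with Adam, L2 penalty,
  and early stopping on validation loss (patience 2).
* **Attribution** — in-silico saturation mutagenesis over random sequences
  (per-position std of prediction shifts) and a pairwise-interaction matrix:
  the mean Euclidean distance between the 9-vector of double-mutation
  effects E_ij and E_i + E_j. Both localize guide toxicity to the 5
  PAM-proximal (seed) bases.
* **Bad-seed statistics** — per-5-mer-seed group means tested one-sided
  against the template-strand reference population, Bonferroni-corrected
  over the 1024 possible seeds; cross-strain OLS of per-seed means
  quantifies the dCas9-concentration dependence of the effect.
* **Off-target detection** — a k-mer index of all NGG sites finds sites
  sharing ≥ k PAM-proximal bases with a guide; the detection-rate curve
  over k = 6..15 (defect vs no-defect guides, important-region hits)
  locates the minimal identity that silences, with a Fisher exact test.
* **Synthetic screen generator** — genomes with operons, promoters and
  essentiality classes; planted bad seeds, off-target pairs, polar
  effects; negative-binomial counts — every effect logged in a truth
  ledger, so the whole pipeline is testable end to end without external
  data.

## Worked example

Run the full pipeline on a default synthetic screen (50 kb genome, 8,000
guides, 20 planted toxic seeds, planted 9-nt off-targets, 3 replicates):

```bash
$ crispri-screen --run-dir run --seed 1 all
simulated 8001 guides over 50000 nt -> run
60 guides discarded; fitness table -> run/fitness.tsv
6698 neutral-region guides of 8001
trained 23 epochs on 5324 guides
test r=0.769 rmse=1.165 (n=666)
mutation attribution written
20 significant bad seeds
978 off-target hits
argmax k = 9 (Fisher p = 1.20e-139)
{
 "detection_argmax_k": 9,
 "n_significant_bad_seeds": 20,
 "n_strong_defect_guides": 1959,
 "test_pearson_r": 0.7687854068698762,
 "test_rmse": 1.165392330602377
}
```

Reading the report: all 20 planted toxic seeds are recovered at Bonferroni
p < 0.01 (`n_significant_bad_seeds`); the sequence model explains held-out
guide fitness at Pearson r = 0.77; and the off-target sweep peaks at a
9-nt seed match (`detection_argmax_k`) — exactly the planted identity
length — with defect guides vastly enriched for important-region
off-targets (Fisher p ≈ 1e-139). Artifacts (fitness table, region BED,
seed statistics, model weights, detection curve) land in `run/`, each
stamped with the run's config hash; `report` refuses to mix stages run
under different configurations.

The same analysis is available in-memory:

```python
from crispri_screen.simulate import SimulationConfig, simulate_screen
from crispri_screen.pipeline import analyze_screen, bad_seed_recovery

screen = simulate_screen(SimulationConfig(rng_seed=1))
analysis = analyze_screen(screen, model_seed=1)
print(analysis.headline)
print(bad_seed_recovery(analysis, screen.truth.bad_seed_tau))
```

For real data, start from `crispri_screen.genome.load_genome` (FASTA +
annotation TSV/GFF3) and `crispri_screen.foldchange.read_counts_tsv`, then
use the same stages.

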