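"""One-call analysis of a screen: the full stage chain in memory.

``analyze_screen`` runs fold-change computation, the position/orientation
tree, neutral-region classification, per-seed statistics with bad-seed
calls, sequence-model training/evaluation, mutation attribution, and the
off-target detection sweep, returning the intermediate objects plus a flat
dict of headline numbers.  The CLI stages wrap the same operations
file-to-file; this entry point serves scripted analyses and the recovery
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .foldchange import compute_log2fc
from .model import evaluate_model, train_model
from .mutagenesis import (
    pairwise_interactions,
    positional_variability,
    seed_interaction_enrichment,
    single_mutation_effects,
)
from .offtargets import (
    best_important_match,
    build_important_classifier,
    detection_rate_curve,
    index_genome_seeds,
    offtarget_fisher_test,
)
from .regions import (
    STRONG_DEFECT_THRESHOLD,
    classify_neutral_guides,
    fit_region_tree,
    template_strand_reference_mean,
)
from .seedstats import bad_seed_test, seed_summary
from .simulate import SimulationResult


@dataclass
class ScreenAnalysis:
    fitness: pd.DataFrame
    region_set: object
    neutral: pd.DataFrame
    seed_calls: pd.DataFrame
    model_bundle: dict | None
    test_pearson: float
    test_rmse: float
    positional_std: np.ndarray | None
    interaction_enrichment: float | None
    curve: object
    fisher_odds: float
    fisher_p: float
    defect_pool: tuple
    headline: dict


def neutral_training_frame(result: SimulationResult, fitness, region_set) -> pd.DataFrame:
    neutral = classify_neutral_guides(region_set, result.guides)
    df = neutral.merge(fitness[["log2fc", "discarded"]], left_on="guide_id",
                       right_index=True)
    return df[~df["discarded"]].reset_index(drop=True)


def defect_pools(result: SimulationResult, fitness,
                 threshold: float = STRONG_DEFECT_THRESHOLD):
    """Template-strand guides in neutral genes, split by strong defect."""
    df = result.guides.merge(fitness[["log2fc", "discarded"]],
                             left_on="guide_id", right_index=True)
    df = df[~df["discarded"] & ~df["is_control"]]
    ess = {a.gene: a.essentiality for a in result.annotations}
    in_neutral = df["target_gene"].map(lambda g: ess.get(g) == "neutral")
    pool = df[(df["orientation"] == "template") & in_neutral.fillna(False)]
    return pool[pool["log2fc"] < threshold], pool[pool["log2fc"] >= threshold]


def analyze_screen(result: SimulationResult, model_seed: int = 0,
                   train: bool = True, attribution: bool = True,
                   n_attr_sequences: int = 1000, n_pair_sequences: int = 100,
                   **model_params) -> ScreenAnalysis:
    fitness = compute_log2fc(result.counts)
    region_set = fit_region_tree(fitness, result.guides,
                                 genome_length=len(result.genome))

    summary = seed_summary(fitness, result.guides, restriction="neutral",
                           region_set=region_set)
    ref = template_strand_reference_mean(fitness, result.guides)
    calls = bad_seed_test(summary, ref)

    neutral_df = neutral_training_frame(result, fitness, region_set)
    bundle, r, rmse = None, float("nan"), float("nan")
    std, enrichment = None, None
    if train:
        bundle = train_model(neutral_df["spacer"], neutral_df["log2fc"],
                             random_state=model_seed, **model_params)
        te = bundle["test"]
        r, rmse = evaluate_model(bundle["model"],
                                 neutral_df["spacer"].iloc[te],
                                 neutral_df["log2fc"].iloc[te])
        if attribution:
            rng = np.random.default_rng(model_seed + 1)
            profile = single_mutation_effects(bundle["model"],
                                              n_sequences=n_attr_sequences,
                                              rng=rng)
            std = positional_variability(profile)
            inter = pairwise_interactions(bundle["model"],
                                          n_sequences=n_pair_sequences, rng=rng)
            enrichment = seed_interaction_enrichment(inter)

    defect, no_defect = defect_pools(result, fitness)
    index = index_genome_seeds(result.genome, 6)
    classifier = build_important_classifier(result.annotations)
    curve = detection_rate_curve(defect, no_defect, index, classifier)
    bd = best_important_match(defect, index, classifier).to_numpy()
    bn = best_important_match(no_defect, index, classifier).to_numpy()
    odds, fisher_p = offtarget_fisher_test(bd, bn, k=9)

    at9 = curve.frame.set_index("k").loc[9]
    headline = {
        "n_significant_bad_seeds": int((calls["call"] == "significant").sum()),
        "test_pearson_r": r,
        "test_rmse": rmse,
        "detection_argmax_k": curve.argmax_k,
        "detection_positive_rate_at_k9": float(at9["positive_rate"]),
        "detection_false_positive_rate_at_k9": float(at9["false_positive_rate"]),
        "fisher_p": fisher_p,
    }
    return ScreenAnalysis(fitness=fitness, region_set=region_set,
                          neutral=neutral_df, seed_calls=calls,
                          model_bundle=bundle, test_pearson=r, test_rmse=rmse,
                          positional_std=std,
                          interaction_enrichment=enrichment, curve=curve,
                          fisher_odds=odds, fisher_p=fisher_p,
                          defect_pool=(defect, no_defect), headline=headline)


def bad_seed_recovery(analysis: ScreenAnalysis, truth_tau: dict) -> dict:
    """Score bad-seed calls against the planted toxicities."""
    calls = analysis.seed_calls
    called = set(calls.index[calls["call"] == "significant"])
    planted = set(truth_tau)
    tested_null = int((calls["call"] != "insufficient").sum()) - \
        len(planted & set(calls.index[calls["call"] != "insufficient"]))
    false_pos = len(called - planted)
    planted_rows = calls.loc[sorted(planted & set(calls.index))]
    taus = np.array([truth_tau[s] for s in planted_rows.index])
    if len(taus) >= 3 and planted_rows["mean"].std() > 0:
        pear = float(sps.pearsonr(planted_rows["mean"], taus)[0])
    else:
        pear = float("nan")
    return {
        "recall": len(called & planted) / len(planted) if planted else float("nan"),
        "n_planted": len(planted),
        "false_positives": false_pos,
        "n_tested_null": tested_null,
        "false_positive_rate": false_pos / tested_null if tested_null else 0.0,
        "planted_mean_tau_pearson": pear,
    }
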