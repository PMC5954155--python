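"""Per-5-mer-seed fitness statistics and bad-seed calling.

Guides are grouped by their 5 PAM-proximal spacer bases; each group's mean
log2FC is tested (one-sided, lower) against the mean of the reference
population — by default all guides targeting the template strand of genes,
which should carry no on-target effect — with Bonferroni correction over
the 4^5 = 1024 possible seeds.  Seeds significantly more depleted than the
reference are "bad seeds".  Comparing per-seed means between two strains
expressing different dCas9 levels quantifies the concentration dependence
of the effect as the slope of an ordinary least-squares regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regions import classify_neutral_guides, template_strand_reference_mean

N_SEED_SPACE = 4 ** 5  # 1024 possible 5-mers, the Bonferroni family size


def _restrict(fitness: pd.DataFrame, guides: pd.DataFrame, restriction: str,
              region_set=None) -> pd.DataFrame:
    df = guides.merge(fitness[["log2fc", "discarded"]], left_on="guide_id",
                      right_index=True, how="inner")
    df = df[~df["discarded"] & ~df["is_control"]]
    if restriction == "all":
        return df
    if restriction == "template":
        return df[df["orientation"] == "template"]
    if restriction == "neutral":
        if region_set is None:
            raise ValueError("restriction='neutral' needs a fitted region set")
        neutral = classify_neutral_guides(region_set, guides)
        return df[df["guide_id"].isin(neutral["guide_id"])]
    raise ValueError(f"unknown restriction {restriction!r}")


def seed_summary(fitness: pd.DataFrame, guides: pd.DataFrame,
                 restriction: str = "neutral", region_set=None,
                 min_group: int = 3) -> pd.DataFrame:
    """Group guides by seed5 and summarize their fitness distribution.

    Returns one row per observed seed: n, mean, std (ddof=1; NaN for
    singleton groups, flagged), and whether the group is testable
    (n >= min_group).  All groups are reported regardless of size.
    """
    df = _restrict(fitness, guides, restriction, region_set)
    grp = df.groupby("seed5")["log2fc"]
    out = pd.DataFrame({
        "n": grp.size(),
        "mean": grp.mean(),
        "std": grp.std(ddof=1),
    })
    out.index.name = "seed"
    out["testable"] = out["n"] >= min_group
    out["exclusion_reason"] = np.where(out["testable"], "", f"n<{min_group}")
    return out.sort_index()


def bad_seed_test(summary: pd.DataFrame, reference_mean: float,
                  alpha: float = 0.01, n_tests: int = N_SEED_SPACE,
                  alternative: str = "less") -> pd.DataFrame:
    """One-sample t-test of each seed group against the reference mean.

    One-sided (lower) by default — the claim under test is reduced fitness —
    with Bonferroni correction over the full 1024-seed space.  Groups with
    n < 3 are called "insufficient".
    """
    out = summary.copy()
    t = (out["mean"] - reference_mean) / (out["std"] / np.sqrt(out["n"]))
    dof = out["n"] - 1
    if alternative == "less":
        p = stats.t.cdf(t, dof)
    elif alternative == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), dof)
    else:
        raise ValueError("alternative must be 'less' or 'two-sided'")
    out["t"] = t
    out["p"] = p
    out["p_bonferroni"] = np.minimum(1.0, p * n_tests)
    call = np.where(
        ~out["testable"], "insufficient",
        np.where((out["p_bonferroni"] < alpha) & (out["mean"] < reference_mean),
                 "significant", "not"),
    )
    out["call"] = call
    out.attrs["reference_mean"] = reference_mean
    return out


def run_seed_analysis(fitness, guides, region_set, restriction: str = "neutral",
                      alpha: float = 0.01) -> pd.DataFrame:
    """Summary + bad-seed calls with the template-strand reference mean."""
    summary = seed_summary(fitness, guides, restriction=restriction,
                           region_set=region_set)
    ref = template_strand_reference_mean(fitness, guides)
    return bad_seed_test(summary, ref, alpha=alpha)


def cross_strain_regression(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                            min_n: int = 3) -> tuple[float, float, float]:
    """OLS of per-seed mean fitness in strain B on strain A.

    Seeds are matched by index; only groups with n >= min_n in both strains
    enter.  Returns (slope, intercept, r_squared).
    """
    joined = stats_a[["n", "mean"]].join(stats_b[["n", "mean"]],
                                         lsuffix="_a", rsuffix="_b", how="inner")
    joined = joined[(joined["n_a"] >= min_n) & (joined["n_b"] >= min_n)].dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} seeds shared between strains; need >= 3")
    res = stats.linregress(joined["mean_a"], joined["mean_b"])
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
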