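"""Region tree, neutral classification, rolling averages, polar tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crispri_screen.genome import GeneAnnotation
from crispri_screen.regions import (
    classify_neutral_guides,
    fit_region_tree,
    polar_effect_test,
    rolling_average,
)


def _guides(positions, log2fc, orientation="coding"):
    """Minimal guide table + fitness table pair for the tree."""
    n = len(positions)
    guides = pd.DataFrame({
        "guide_id": [f"g{i}" for i in range(n)],
        "spacer": ["A" * 20] * n,
        "pam_pos": positions,
        "strand": ["+"] * n,
        "seed5": ["A" * 5] * n,
        "orientation": [orientation] * n,
        "multi_mapping": False,
        "is_control": False,
    })
    fitness = pd.DataFrame({
        "log2fc": log2fc,
        "discarded": False,
    }, index=pd.Index(guides["guide_id"], name="guide_id"))
    return guides, fitness


def greedy_exhaustive_tree(x, y, max_depth, min_leaf):
    """Independent oracle: recursive exhaustive-search variance-minimizing
    partition (same objective as CART, scanned split-by-split in python).

    Returns leaf assignment labels for each point.
    """
    order = np.argsort(x, kind="stable")
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    labels = np.zeros(len(x), dtype=int)
    counter = [0]

    def sse(v):
        return ((v - v.mean()) ** 2).sum() if len(v) else 0.0

    def split(lo, hi, depth):
        n = hi - lo
        if depth == 0 or n < 2 * min_leaf:
            counter[0] += 1
            labels[lo:hi] = counter[0]
            return
        best, best_i = None, None
        for i in range(lo + min_leaf, hi - min_leaf + 1):
            if x[i] == x[i - 1]:
                continue  # cannot split between equal positions
            cost = sse(y[lo:i]) + sse(y[i:hi])
            if best is None or cost < best - 1e-12:
                best, best_i = cost, i
        if best is None or best >= sse(y[lo:hi]) - 1e-12:
            counter[0] += 1
            labels[lo:hi] = counter[0]
            return
        split(lo, best_i, depth - 1)
        split(best_i, hi, depth - 1)

    split(0, len(x), max_depth)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return labels[inverse]


class TestRegionTree:
    def test_matches_exhaustive_search_partition(self, rng):
        """For small inputs and shallow depth, CART splits equal the
        exhaustive variance-minimizing splits (compared as partitions)."""
        for trial in range(20):
            n = int(rng.integers(12, 50))
            x = np.sort(rng.choice(np.arange(500), size=n, replace=False))
            y = rng.normal(size=n)
            guides, fitness = _guides(x, y)
            region_set = fit_region_tree(fitness, guides, min_leaf=3,
                                         max_depth=2, genome_length=500)
            pred = region_set.predict(x, np.array(["coding"] * n, dtype=object))
            oracle_labels = greedy_exhaustive_tree(x, y, max_depth=2, min_leaf=3)
            # same partition -> identical leaf means per point
            oracle_pred = np.empty(n)
            for lab in np.unique(oracle_labels):
                m = oracle_labels == lab
                oracle_pred[m] = y[m].mean()
            assert np.allclose(pred, oracle_pred, atol=1e-9), f"trial {trial}"

    def test_zero_variance_gives_single_leaf(self):
        guides, fitness = _guides(np.arange(0, 300, 10), np.zeros(30))
        region_set = fit_region_tree(fitness, guides, genome_length=300)
        leaves = region_set.regions
        assert len(leaves) == 1
        assert leaves.iloc[0]["predicted"] == 0.0

    def test_leaf_predictions_equal_member_means(self, rng):
        x = rng.choice(np.arange(2000), size=120, replace=False)
        y = rng.normal(size=120) + np.where(x < 800, -4.0, 0.0)
        guides, fitness = _guides(x, y)
        region_set = fit_region_tree(fitness, guides, min_leaf=10,
                                     genome_length=2000)
        pred = region_set.predict(x, np.array(["coding"] * 120, dtype=object))
        for _, leaf in region_set.regions.iterrows():
            m = (x >= leaf.start) & (x < leaf.end)
            if m.sum():
                assert y[m].mean() == pytest.approx(pred[m][0], abs=1e-9)

    def test_planted_block_boundaries_recovered(self, rng):
        """An essential block at [10k, 12k) is carved out within min_leaf
        guides of its true edges."""
        min_leaf = 10
        x = np.sort(rng.choice(np.arange(50_000), size=4000, replace=False))
        in_block = (x >= 10_000) & (x < 12_000)
        y = rng.normal(0, 0.3, size=4000) + np.where(in_block, -5.0, 0.0)
        guides, fitness = _guides(x, y)
        region_set = fit_region_tree(fitness, guides, min_leaf=min_leaf,
                                     genome_length=50_000)
        important = region_set.regions[region_set.regions.predicted <= -3.5]
        assert len(important) >= 1
        lo = important.start.min()
        hi = important.end.max()
        # boundary tolerance: the coordinate span of min_leaf guides
        assert abs(lo - 10_000) <= 10_000 - x[x < 10_000][-min_leaf]
        assert abs(hi - 12_000) <= x[x >= 12_000][min_leaf] - 12_000

    def test_neutral_classification_against_truth(self, rng):
        x = np.sort(rng.choice(np.arange(50_000), size=4000, replace=False))
        in_block = (x >= 10_000) & (x < 12_000)
        y = rng.normal(0, 0.3, size=4000) + np.where(in_block, -5.0, 0.0)
        guides, fitness = _guides(x, y)
        region_set = fit_region_tree(fitness, guides, min_leaf=10,
                                     genome_length=50_000)
        neutral = classify_neutral_guides(region_set, guides)
        predicted_neutral = guides["guide_id"].isin(neutral["guide_id"])
        agreement = (predicted_neutral == ~in_block).mean()
        assert agreement >= 0.95

    def test_trivial_leaf_membership(self):
        guides, fitness = _guides([10, 20, 30, 1000, 1010, 1020],
                                  [0, 0, 0, -5, -5, -5])
        region_set = fit_region_tree(fitness, guides, min_leaf=1,
                                     genome_length=2000)
        neutral = classify_neutral_guides(region_set, guides)
        assert set(neutral["guide_id"]) == {"g0", "g1", "g2"}

    def test_empty_input_rejected(self):
        guides, fitness = _guides([], [])
        with pytest.raises(ValueError):
            fit_region_tree(fitness, guides)


class TestRollingAverage:
    def test_constant_series(self):
        out = rolling_average(np.arange(50), np.full(50, 3.0), window=7)
        assert np.allclose(out["mean"], 3.0)
        assert np.allclose(out["std"], 0.0)

    def test_hand_arithmetic_window(self):
        out = rolling_average([0, 10, 20], [1, 2, 3], window=21)
        mid = out[out.position == 10].iloc[0]
        assert mid["mean"] == pytest.approx(2.0)  # all three points covered
        edge = out[out.position == 0].iloc[0]
        assert edge["mean"] == pytest.approx(1.5)  # points at 0 and 10

    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            pos = rng.uniform(0, 500, size=n)
            val = rng.normal(size=n)
            window = float(rng.uniform(1, 120))
            out = rolling_average(pos, val, window)
            order = np.argsort(pos, kind="stable")
            spos, sval = pos[order], val[order]
            for i, p in enumerate(out["position"]):
                member = np.abs(spos - p) <= window / 2 + 1e-12
                assert out["mean"].iloc[i] == pytest.approx(sval[member].mean())
                assert out["std"].iloc[i] == pytest.approx(sval[member].std())

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            rolling_average([0], [1], window=0)


def _polar_setup(near_values, far_values, ref_values, rng):
    """One terminal essential '+' gene at [1000, 2000); guides planted in its
    downstream windows plus template-strand reference guides in a neutral
    gene."""
    anns = [
        GeneAnnotation("ess", 1000, 2000, "+", "essential", "op1"),
        GeneAnnotation("neu", 3000, 4000, "+", "neutral", "op2"),
    ]
    rows, fit = [], {}
    for i, v in enumerate(near_values):
        gid = f"n{i}"
        pam = int(2000 + rng.integers(0, 99)) + 1  # proximal base in [2000, 2100)
        rows.append((gid, pam, "+", "intergenic", None))
        fit[gid] = v
    for i, v in enumerate(far_values):
        gid = f"f{i}"
        pam = int(2100 + rng.integers(0, 99)) + 1
        rows.append((gid, pam, "+", "intergenic", None))
        fit[gid] = v
    for i, v in enumerate(ref_values):
        gid = f"r{i}"
        pam = int(3000 + rng.integers(0, 980))
        rows.append((gid, pam, "-", "template", "neu"))
        fit[gid] = v
    guides = pd.DataFrame(rows, columns=["guide_id", "pam_pos", "strand",
                                         "orientation", "target_gene"])
    guides["spacer"] = "A" * 20
    guides["seed5"] = "A" * 5
    guides["multi_mapping"] = False
    guides["is_control"] = False
    fitness = pd.DataFrame({"log2fc": pd.Series(fit), "discarded": False})
    fitness.index.name = "guide_id"
    return guides, fitness, anns


class TestPolarEffectTest:
    def test_t_statistic_matches_closed_form(self, rng):
        vals = [0.1, -0.4, -0.9, -0.2, -0.6]
        ref = [0.0] * 20
        guides, fitness, anns = _polar_setup(vals, [], ref, rng)
        out = polar_effect_test(fitness, guides, anns)
        near = out.iloc[0]
        mu = np.mean(ref)
        expected_t = (np.mean(vals) - mu) / (np.std(vals, ddof=1) / np.sqrt(5))
        assert near["n"] == 5
        assert near["t"] == pytest.approx(expected_t)
        assert near["p"] == pytest.approx(
            2 * stats.t.sf(abs(expected_t), 4))

    def test_equal_to_reference_gives_t_zero(self, rng):
        guides, fitness, anns = _polar_setup([0.5] * 4, [], [0.5] * 10, rng)
        out = polar_effect_test(fitness, guides, anns)
        assert out.iloc[0]["t"] == pytest.approx(0.0)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_simulated_weak_polar_power(self, rng):
        """-0.5 planted in the near window only: near significant, far not."""
        near = rng.normal(-0.5, 0.5, size=250)
        far = rng.normal(0.0, 0.5, size=250)
        ref = rng.normal(0.0, 0.5, size=500)
        guides, fitness, anns = _polar_setup(near, far, ref, rng)
        out = polar_effect_test(fitness, guides, anns)
        assert out.iloc[0]["p"] < 0.01
        assert out.iloc[0]["direction"] == "below_reference"
        assert out.iloc[1]["p"] > 0.05

    def test_small_windows_report_nan(self, rng):
        guides, fitness, anns = _polar_setup([0.1, 0.2], [], [0.0] * 5, rng)
        out = polar_effect_test(fitness, guides, anns)
        assert np.isnan(out.iloc[0]["p"])


class TestScreenLevelSummary:
    def test_strand_asymmetry_of_essential_gene_guides(self, small_sim, small_fitness):
        """Coding-strand guides in essential genes are depleted; template-
        strand guides there look like neutral-gene guides."""
        df = small_sim.guides.merge(
            small_fitness[["log2fc", "discarded"]],
            left_on="guide_id", right_index=True)
        df = df[~df["discarded"] & ~df["is_control"]]
        ess = {a.gene: a.essentiality for a in small_sim.annotations}
        in_ess = df["target_gene"].map(lambda g: ess.get(g) == "essential")
        in_neu = df["target_gene"].map(lambda g: ess.get(g) == "neutral")
        coding_ess = df[(df.orientation == "coding") & in_ess]["log2fc"].mean()
        templ_ess = df[(df.orientation == "template") & in_ess]["log2fc"].mean()
        neutral = df[(df.orientation == "template") & in_neu]["log2fc"].mean()
        assert coding_ess < templ_ess - 3
        assert abs(templ_ess - neutral) < 1.0
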