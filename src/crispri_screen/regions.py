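"""Positional analyses: important-region tree, rolling averages, polar tests.

A CART regression tree predicts log2FC from the PAM position along the
genome, fitted separately for each target-orientation class.  Its leaves
partition the genome (per orientation) into intervals of consistent fitness
effect; leaves predicting at most the strong-defect threshold (default
log2FC <= -3.5) define the "important regions", and guides in the remaining
leaves are the neutral-region set used for sequence modelling and bad-seed
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .simulate import terminal_important_genes

STRONG_DEFECT_THRESHOLD = -3.5


@dataclass
class ImportantRegionSet:
    """Per-orientation genomic segmentation by predicted log2FC.

    ``regions`` columns: orientation, start, end, n_guides, predicted.
    Leaves with ``predicted`` <= ``threshold`` are the important regions.
    """

    regions: pd.DataFrame
    threshold: float
    genome_length: int
    trees: dict = field(default_factory=dict, repr=False)

    def predict(self, pam_pos, orientation) -> np.ndarray:
        """Leaf prediction for arrays of positions and orientation labels."""
        pam_pos = np.asarray(pam_pos, dtype=float)
        orientation = np.asarray(orientation, dtype=object)
        out = np.zeros(len(pam_pos))
        for orient, tree in self.trees.items():
            m = orientation == orient
            if m.any():
                out[m] = tree.predict(pam_pos[m, None])
        return out

    def to_bed(self, genome_id: str, path):
        """One BED track line per leaf; score column holds the prediction."""
        with open(path, "w") as fh:
            for row in self.regions.itertuples(index=False):
                fh.write(f"{genome_id}\t{int(row.start)}\t{int(row.end)}\t"
                         f"{row.orientation}\t{row.predicted:.3f}\t.\n")


def _merged(fitness: pd.DataFrame, guides: pd.DataFrame) -> pd.DataFrame:
    df = guides.merge(fitness[["log2fc", "discarded"]], left_on="guide_id",
                      right_index=True, how="inner")
    return df[~df["discarded"] & ~df["is_control"]]


def fit_region_tree(fitness: pd.DataFrame, guides: pd.DataFrame,
                    min_leaf: int = 10, max_depth: int = 14,
                    genome_length: int | None = None,
                    threshold: float = STRONG_DEFECT_THRESHOLD) -> ImportantRegionSet:
    """Fit the position/orientation regression tree.

    Variance-reduction (CART) splits on PAM position, one tree per
    orientation class; leaf predictions are the mean log2FC of member
    guides.  Multi-mapping guides are excluded (their position is
    undefined).
    """
    df = _merged(fitness, guides)
    df = df[~df["multi_mapping"]]
    if df.empty:
        raise ValueError("no usable guides to fit the region tree")
    if genome_length is None:
        genome_length = int(df["pam_pos"].max()) + 1

    trees: dict[str, DecisionTreeRegressor] = {}
    rows = []
    for orient, grp in df.groupby("orientation"):
        X = grp["pam_pos"].to_numpy(dtype=float)[:, None]
        y = grp["log2fc"].to_numpy()
        tree = DecisionTreeRegressor(max_depth=max_depth,
                                     min_samples_leaf=min(min_leaf, len(grp)),
                                     random_state=0)
        tree.fit(X, y)
        trees[orient] = tree
        thr = tree.tree_.threshold[tree.tree_.feature == 0]
        bounds = np.concatenate([[0.0], np.sort(thr), [float(genome_length)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            mid = (lo + hi) / 2.0
            pred = float(tree.predict([[mid]])[0])
            n = int(((X[:, 0] > lo) & (X[:, 0] <= hi)).sum()) if lo > 0 else \
                int(((X[:, 0] >= lo) & (X[:, 0] <= hi)).sum())
            rows.append((orient, int(np.floor(lo)), int(np.ceil(hi)), n, pred))
    regions = pd.DataFrame(rows, columns=["orientation", "start", "end",
                                          "n_guides", "predicted"])
    # merge adjacent leaves with identical predictions (cosmetic only)
    return ImportantRegionSet(regions=regions, threshold=threshold,
                              genome_length=genome_length, trees=trees)


def classify_neutral_guides(region_set: ImportantRegionSet, guides: pd.DataFrame,
                            threshold: float | None = None) -> pd.DataFrame:
    """Guides whose leaf prediction exceeds the strong-defect threshold.

    The complement (prediction <= threshold) defines the important-region
    guide set.  Control and multi-mapping guides are never classified
    neutral here (no usable position).
    """
    if threshold is None:
        threshold = region_set.threshold
    usable = ~guides["is_control"] & ~guides["multi_mapping"]
    sub = guides[usable]
    pred = region_set.predict(sub["pam_pos"], sub["orientation"])
    return sub[pred > threshold]


def rolling_average(positions, values, window: float) -> pd.DataFrame:
    """Centered rolling mean/std of values keyed by coordinate.

    At each data coordinate p (sorted), aggregates the values with
    coordinate in [p - window/2, p + window/2].  Windows are defined over
    the coordinate axis, not over ranks, so uneven spacing is respected.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, val = pos[order], val[order]
    half = window / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    mean = np.empty(len(pos))
    std = np.empty(len(pos))
    n = hi - lo
    for i in range(len(pos)):
        w = val[lo[i]:hi[i]]
        mean[i] = w.mean()
        std[i] = w.std()
    return pd.DataFrame({"position": pos, "mean": mean, "std": std, "n": n})


def template_strand_reference_mean(fitness: pd.DataFrame, guides: pd.DataFrame) -> float:
    """Mean log2FC of guides targeting the template strand of genes — the
    null population used as reference by the polar and bad-seed tests."""
    df = _merged(fitness, guides)
    ref = df[df["orientation"] == "template"]["log2fc"]
    if ref.empty:
        raise ValueError("no template-strand guides to form a reference")
    return float(ref.mean())


def polar_effect_test(fitness: pd.DataFrame, guides: pd.DataFrame, annotations,
                      near: tuple = (0, 100), far: tuple = (100, 200),
                      gene_list=None) -> pd.DataFrame:
    """Reverse-polar test: effect of coding-strand guides just past the stop
    codon of terminal essential/fitness genes.

    For each window (in nt downstream of the gene 3' end, gene orientation),
    a two-sided one-sample t-test of member guides' log2FC against the mean
    of template-strand guides in gene bodies.  ``gene_list`` defaults to the
    essential/fitness genes not followed by another essential/fitness gene.
    Windows with fewer than 3 guides report p = NaN.
    """
    if gene_list is None:
        gene_list = terminal_important_genes(annotations)
    df = _merged(fitness, guides)
    ref_mean = template_strand_reference_mean(fitness, guides)

    from .genome import pam_proximal_base
    pos = df.apply(lambda r: pam_proximal_base(r["pam_pos"], r["strand"]), axis=1)
    rows = []
    for lo, hi in (near, far):
        mask = np.zeros(len(df), dtype=bool)
        for t in gene_list:
            if t.strand == "+":
                d = pos - t.end
            else:
                d = t.start - 1 - pos
            mask |= ((df["strand"] == t.strand) & (d >= lo) & (d < hi)).to_numpy()
        vals = df.loc[mask, "log2fc"].to_numpy()
        n = len(vals)
        if n >= 3:
            if np.std(vals, ddof=1) == 0.0:
                # degenerate sample: all values identical
                eq = vals[0] == ref_mean
                t_stat = 0.0 if eq else np.sign(vals[0] - ref_mean) * np.inf
                p = 1.0 if eq else 0.0
            else:
                t_stat, p = stats.ttest_1samp(vals, popmean=ref_mean)
                t_stat, p = float(t_stat), float(p)
        else:
            t_stat, p = np.nan, np.nan
        mean = float(vals.mean()) if n else np.nan
        rows.append(((lo, hi), n, mean, t_stat, p,
                     "below_reference" if n and mean < ref_mean else "at_or_above"))
    return pd.DataFrame(rows, columns=["window", "n", "mean", "t", "p", "direction"])
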