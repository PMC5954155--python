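"""Guide read counts to normalized per-guide log2 fold changes.

Size factors are median-of-ratios (the classical count-normalization
estimator): factor_j = median over guides of count_gj / geometric-mean_g,
computed over guides with non-zero counts in every sample.  Per replicate,

    log2FC_g = log2((end_g/sf_end + p) / (start_g/sf_start + p))
             - [same quantity for the control guide]

with pseudocount p so that end-depleted guides (the signal of interest) stay
finite, and the reported log2FC is the mean across replicates.  Guides with
fewer than ``min_total_reads`` reads summed over all samples are discarded.
No per-guide dispersion shrinkage or Wald testing is performed; downstream
analyses consume the point log2FC only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CONTROL_SPACER

_SAMPLE_RE = re.compile(r"^(start|end)_(\d+)$")


@dataclass
class CountTable:
    """Integer read counts, guides x samples.

    Sample columns are named ``start_<r>`` / ``end_<r>`` for replicate r;
    every replicate must have both timepoints.  ``spacers`` optionally maps
    guide_id to spacer sequence (used to locate the control guide).
    """

    counts: pd.DataFrame
    spacers: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("guide ids are not unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        reps: dict[str, set] = {}
        for col in self.counts.columns:
            m = _SAMPLE_RE.match(col)
            if not m:
                raise ValueError(f"sample column {col!r} not of form start_<r>/end_<r>")
            reps.setdefault(m.group(2), set()).add(m.group(1))
        for r, tps in reps.items():
            if tps != {"start", "end"}:
                raise ValueError(f"replicate {r} lacks a start or end timepoint")
        self.replicates = sorted(reps, key=int)

    def control_id(self, control_spacer: str = CONTROL_SPACER) -> str:
        """Guide id of the control guide, located by spacer or by id."""
        if self.spacers is not None:
            match = self.spacers[self.spacers == control_spacer]
            if len(match):
                return str(match.index[0])
        if "control" in self.counts.index:
            return "control"
        raise ValueError(
            f"control guide (spacer {control_spacer}) absent from the count table"
        )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Guides with a zero count in any sample are excluded from the median.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no guide has non-zero counts in every sample; sequencing depth "
            "may be too low to estimate size factors"
        )
    log_geo = np.log(mat[allpos]).mean(axis=1, keepdims=True)
    ratios = mat[allpos] / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def compute_log2fc(counts: CountTable, control_spacer: str = CONTROL_SPACER,
                   min_total_reads: int = 20, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-guide log2 fold change, normalized to the control guide.

    Returns the fitness table: index guide_id, columns ``log2fc`` (mean over
    replicates), ``log2fc_r<r>`` per replicate, ``discarded`` and ``reason``.
    Discarded guides carry NaN log2fc.
    """
    ctrl = counts.control_id(control_spacer)
    sf = size_factors(counts.counts)
    mat = counts.counts
    total = mat.sum(axis=1)
    discarded = total < min_total_reads
    if discarded.loc[ctrl]:
        raise ValueError("control guide fails the minimum-read filter; cannot normalize")

    out = pd.DataFrame(index=mat.index)
    rep_cols = []
    for r in counts.replicates:
        norm_start = mat[f"start_{r}"] / sf[f"start_{r}"]
        norm_end = mat[f"end_{r}"] / sf[f"end_{r}"]
        l2 = np.log2(norm_end + pseudocount) - np.log2(norm_start + pseudocount)
        l2 = l2 - l2.loc[ctrl]
        col = f"log2fc_r{r}"
        out[col] = l2
        rep_cols.append(col)
    out.insert(0, "log2fc", out[rep_cols].mean(axis=1))
    out.loc[discarded, ["log2fc"] + rep_cols] = np.nan
    out["discarded"] = discarded
    out["reason"] = np.where(discarded, f"total_reads<{min_total_reads}", "")
    out.attrs["control_id"] = ctrl
    return out


def write_counts_tsv(counts: CountTable, path, header_lines=()):
    frame = counts.counts.copy()
    if counts.spacers is not None:
        frame.insert(0, "spacer", counts.spacers.reindex(frame.index))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t")


def read_counts_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="guide_id")
    spacers = None
    if "spacer" in df.columns:
        spacers = df.pop("spacer")
    return CountTable(counts=df.astype(int), spacers=spacers)


def write_fitness_tsv(fitness: pd.DataFrame, path, header_lines=(), decimals: int = 2):
    """Write the fitness table with two-decimal display (full precision is an
    in-memory property; the TSV is a report)."""
    frame = fitness.copy()
    num = [c for c in frame.columns if c.startswith("log2fc")]
    frame[num] = frame[num].round(decimals)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t")


def read_fitness_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="guide_id")
    df["discarded"] = df["discarded"].astype(bool)
    df["reason"] = df["reason"].fillna("")
    return df
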