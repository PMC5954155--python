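"""In-silico mutagenesis attribution on a trained sequence model.

Single-mutation scan: over a set of random sequences, every position is
mutated to each alternative base and the shift in model prediction is
recorded; the per-position standard deviation of these shifts measures how
much the model relies on that position.

Pairwise scan: for every position pair (i, j) of each random sequence, the
9 double mutants are compared with the sums of the corresponding single
mutants.  The Euclidean distance between the 9-vector of double-mutation
effects E_ij and the 9-vector E_i + E_j, averaged over sequences, measures
epistatic (non-additive) interaction learned by the model; a model linear
in the one-hot encoding scores exactly zero everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .model import BASES, encode_batch

_ALT = {b: [a for a in BASES if a != b] for b in BASES}


def random_sequences(n: int, length: int, rng) -> list[str]:
    """n i.i.d. uniform ACGT sequences."""
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(BASES[i] for i in row) for row in idx]


def _seq_length(model, seq_length=None) -> int:
    if seq_length is not None:
        return int(seq_length)
    return int(model.n_features_in_) // 4


@dataclass
class MutationEffectProfile:
    """Raw single-mutation effects.

    ``deltas[s, p, b]`` is the prediction shift for sequence s when position
    p is set to base BASES[b]; mutating a base to itself is identically 0.
    """

    deltas: np.ndarray
    sequences: list[str]

    @property
    def n_sequences(self) -> int:
        return self.deltas.shape[0]

    @property
    def length(self) -> int:
        return self.deltas.shape[1]


@dataclass
class InteractionMatrix:
    """Symmetric position x position mean distance between double-mutation
    effects and summed single-mutation effects (diagonal zero)."""

    matrix: np.ndarray
    n_sequences: int
    mode: str = "vector9"

    def to_frame(self) -> pd.DataFrame:
        L = self.matrix.shape[0]
        pos = np.arange(1, L + 1)  # spacer coordinates, PAM-proximal = L
        return pd.DataFrame(self.matrix, index=pos, columns=pos)


def single_mutation_effects(model, n_sequences: int = 1000, rng=None,
                            seq_length: int | None = None,
                            sequences=None) -> MutationEffectProfile:
    """Scan every position x alternative base over random sequences."""
    rng = np.random.default_rng(rng)
    L = _seq_length(model, seq_length)
    seqs = sequences if sequences is not None else random_sequences(n_sequences, L, rng)
    X0 = encode_batch(seqs)
    base_pred = model.predict(X0)
    n = len(seqs)
    deltas = np.zeros((n, L, 4))
    for p in range(L):
        for bi, b in enumerate(BASES):
            X = X0.copy()
            X[:, 4 * p:4 * p + 4] = 0.0
            X[:, 4 * p + bi] = 1.0
            deltas[:, p, bi] = model.predict(X) - base_pred
    return MutationEffectProfile(deltas=deltas, sequences=list(seqs))


def positional_variability(profile: MutationEffectProfile) -> np.ndarray:
    """Per-position std of mutation effects (actual mutations only).

    Each position contributes 3 * n_sequences effects (the three alternative
    bases per sequence); self-mutations are excluded.
    """
    n, L, _ = profile.deltas.shape
    out = np.empty(L)
    orig = np.array([[c for c in s] for s in profile.sequences])
    for p in range(L):
        vals = []
        for bi, b in enumerate(BASES):
            keep = orig[:, p] != b
            vals.append(profile.deltas[keep, p, bi])
        out[p] = np.concatenate(vals).std()
    return out


def variability_frame(std: np.ndarray, pam_offset: int | None = None) -> pd.DataFrame:
    """Tabulate per-position std with spacer coordinates (PAM-proximal = L)."""
    L = len(std)
    df = pd.DataFrame({"position": np.arange(1, L + 1), "std": std})
    df["pam_proximal_rank"] = L - df["position"] + 1
    if pam_offset is not None:
        df["window_position"] = df["position"] + pam_offset
    return df


def pairwise_interactions(model, n_sequences: int = 100, rng=None,
                          seq_length: int | None = None, sequences=None,
                          mode: str = "vector9") -> InteractionMatrix:
    """Average non-additivity between all position pairs.

    ``mode`` "vector9" (default) compares the 9-vector of double-mutation
    effects to the 9-vector of summed singles by Euclidean distance;
    "scalar" averages |E_ij - E_i - E_j| over the 9 base combinations
    instead.
    """
    if mode not in ("vector9", "scalar"):
        raise ValueError("mode must be 'vector9' or 'scalar'")
    rng = np.random.default_rng(rng)
    L = _seq_length(model, seq_length)
    seqs = sequences if sequences is not None else random_sequences(n_sequences, L, rng)
    pairs = list(combinations(range(L), 2))
    acc = np.zeros((L, L))
    for s in seqs:
        x0 = encode_batch([s])[0]
        p0 = model.predict(x0[None, :])[0]
        # singles: (position, alt-rank 0..2)
        singles = np.zeros((L, 3))
        xs = []
        for p in range(L):
            for b in _ALT[s[p]]:
                x = x0.copy()
                x[4 * p:4 * p + 4] = 0.0
                x[4 * p + BASES.index(b)] = 1.0
                xs.append(x)
        pred = model.predict(np.array(xs)) - p0
        singles = pred.reshape(L, 3)
        # doubles
        xd = []
        for i, j in pairs:
            for bi, bj in product(_ALT[s[i]], _ALT[s[j]]):
                x = x0.copy()
                x[4 * i:4 * i + 4] = 0.0
                x[4 * i + BASES.index(bi)] = 1.0
                x[4 * j:4 * j + 4] = 0.0
                x[4 * j + BASES.index(bj)] = 1.0
                xd.append(x)
        dpred = (model.predict(np.array(xd)) - p0).reshape(len(pairs), 3, 3)
        for pi, (i, j) in enumerate(pairs):
            expected = singles[i][:, None] + singles[j][None, :]
            diff = dpred[pi] - expected
            if mode == "vector9":
                d = float(np.sqrt(np.sum(diff ** 2)))
            else:
                d = float(np.mean(np.abs(diff)))
            acc[i, j] += d
            acc[j, i] += d
    acc /= len(seqs)
    np.fill_diagonal(acc, 0.0)
    return InteractionMatrix(matrix=acc, n_sequences=len(seqs), mode=mode)


def seed_interaction_enrichment(interactions: InteractionMatrix,
                                seed_len: int = 5) -> float:
    """Ratio of mean interaction inside the PAM-proximal seed block to the
    mean over all other off-diagonal pairs."""
    m = interactions.matrix
    L = m.shape[0]
    seed = np.arange(L - seed_len, L)
    iu = np.triu_indices(L, k=1)
    in_seed = np.isin(iu[0], seed) & np.isin(iu[1], seed)
    seed_mean = m[iu][in_seed].mean()
    other_mean = m[iu][~in_seed].mean()
    return float(seed_mean / other_mean) if other_mean > 0 else float("inf")
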