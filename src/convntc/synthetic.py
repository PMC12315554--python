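"""Planted-structure synthetic data generators.

The generator emulates the statistical shape the two-stage model assumes: a
third-order binary tensor, symmetric in its first two modes, whose positive
cells are the top quantile of a planted low-rank multilinear score
s(i, j, k) = sum_l M*_il M*_jl D*_kl (mirroring threshold binarization of a
continuous synergy score), together with similarity matrices derived from the
same planted factors plus symmetric noise.  Defaults are the desk-scale study
conditions used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import TripletDataset, SimilarityMatrix
from .mctd import reconstruct_cp

__all__ = ["SyntheticSpec", "GroundTruth", "gen_planted", "gen_toy_tensor"]


@dataclass
class SyntheticSpec:
    """Study conditions for a planted dataset.

    pos_frac is the fraction of canonical (i < j) cells labeled positive;
    obs_frac the fraction of positives revealed to the model; sim_noise the
    s.d. of the symmetric perturbation added to the factor-derived
    similarities.
    """

    n_A: int = 40
    n_B: int = 15
    r_true: int = 4
    pos_frac: float = 0.05
    sim_noise: float = 0.05
    obs_frac: float = 0.8
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.pos_frac < 0.5:
            raise ValueError("pos_frac must lie in (0, 0.5)")
        if self.r_true < 1:
            raise ValueError("r_true must be >= 1")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be >= 0")


@dataclass
class GroundTruth:
    M: np.ndarray
    D: np.ndarray
    positives: set        # all planted-positive canonical cells
    scores: np.ndarray    # full planted score tensor


def _factor_similarity(F: np.ndarray, noise: float, rng) -> SimilarityMatrix:
    """Cosine-normalized F F^T plus symmetric noise, min-max scaled to [0, 1]."""
    G = F @ F.T
    d = np.sqrt(np.clip(np.diag(G), 1e-12, None))
    S = G / np.outer(d, d)
    if noise > 0:
        N = rng.normal(scale=noise, size=S.shape)
        S = S + 0.5 * (N + N.T)
    lo, hi = S.min(), S.max()
    if hi > lo:
        S = (S - lo) / (hi - lo)
    return SimilarityMatrix(0.5 * (S + S.T))


def gen_planted(spec: SyntheticSpec
                ) -> tuple[TripletDataset, SimilarityMatrix, SimilarityMatrix,
                           GroundTruth]:
    """Draw planted factors, threshold the multilinear score, reveal a sample.

    Returns the revealed dataset (obs_frac of the positives plus an equal
    number of sampled negatives), both similarity matrices, and the ground
    truth (factors, full positive set, full score grid).
    """
    rng = np.random.default_rng(spec.seed)
    M = rng.uniform(size=(spec.n_A, spec.r_true))
    D = rng.uniform(size=(spec.n_B, spec.r_true))
    scores = reconstruct_cp(M, M, D)

    cells = [(i, j, k)
             for i in range(spec.n_A)
             for j in range(i + 1, spec.n_A)
             for k in range(spec.n_B)]
    vals = np.array([scores[c] for c in cells])
    n_pos = int(round(spec.pos_frac * len(cells)))
    if n_pos < 1:
        raise ValueError("pos_frac too small: no positive cells")
    # descending score, lexicographic tie-break via stable sort on -value
    order = np.argsort(-vals, kind="stable")
    pos_cells = [cells[t] for t in order[:n_pos]]
    positives = set(pos_cells)

    n_reveal = int(round(spec.obs_frac * n_pos))
    revealed = [pos_cells[t] for t in
                sorted(rng.choice(n_pos, size=n_reveal, replace=False))]
    neg_pool = [cells[t] for t in order[n_pos:]]
    negs = [neg_pool[t] for t in
            sorted(rng.choice(len(neg_pool), size=n_reveal, replace=False))]

    ds = TripletDataset(
        revealed + negs,
        np.concatenate([np.ones(n_reveal, dtype=int), np.zeros(n_reveal, dtype=int)]),
        spec.n_A, spec.n_B,
    )
    Sm = _factor_similarity(M, spec.sim_noise, rng)
    Sd = _factor_similarity(D, spec.sim_noise, rng)
    return ds, Sm, Sd, GroundTruth(M=M, D=D, positives=positives, scores=scores)


def gen_toy_tensor(n_A: int, n_B: int, r: int, seed: int = 0
                   ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Exact rank-r tensor with known independent factors, for identity tests."""
    rng = np.random.default_rng(seed)
    M = rng.uniform(size=(n_A, r))
    C = rng.uniform(size=(n_A, r))
    D = rng.uniform(size=(n_B, r))
    return reconstruct_cp(M, C, D), (M, C, D)
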