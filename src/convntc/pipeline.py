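"""Two-stage orchestration and score post-processing.

Runs the multilinear stage (MCTD) and the neural stage (NTD) on the same
training triplets, scores arbitrary cells with either stage, derives pairwise
scores from triplet scores (A-A and A-B modes) and builds the top-fraction
pair network by aggregating scores over the context dimension.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import TripletDataset, SimilarityMatrix, build_tensor
from .mctd import MCTDHyperparams, FactorSet, mctd_fit, score_cells
from .ntd import NTDModel, TrainConfig, init_ntd_model, ntd_train, predict_batch

__all__ = ["ConvNTCConfig", "ConvNTCRun", "run_convntc", "score_triplets",
           "derive_pair_scores", "build_pair_network"]


@dataclass
class ConvNTCConfig:
    """Full run configuration: both stages plus the mixing weight gamma."""

    mctd: MCTDHyperparams = field(default_factory=MCTDHyperparams)
    train: TrainConfig = field(default_factory=TrainConfig)
    gamma: float = 0.5
    n_channels: int = 16
    n_grid: int = 8

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ConvNTCRun:
    config: ConvNTCConfig
    factors: FactorSet
    model: NTDModel
    mctd_diagnostics: dict
    train_log: dict
    provenance: dict


def run_convntc(ds: TripletDataset, Sm: SimilarityMatrix, Sd: SimilarityMatrix,
                cfg: ConvNTCConfig) -> ConvNTCRun:
    """Fit MCTD on the training tensor, then train NTD on the same triplets."""
    t0 = time.time()
    X = build_tensor(ds)
    factors, diag = mctd_fit(X, Sm, Sd, cfg.mctd)
    model = init_ntd_model(factors, ds.n_A, ds.n_B,
                           n_channels=cfg.n_channels, n_grid=cfg.n_grid,
                           gamma=cfg.gamma, seed=cfg.train.seed)
    model, log = ntd_train(ds, model, cfg.train)
    provenance = {
        "config_hash": cfg.config_hash(),
        "mctd_seed": cfg.mctd.seed,
        "train_seed": cfg.train.seed,
        "started": t0,
        "elapsed_s": time.time() - t0,
        "n_train_triplets": len(ds),
    }
    return ConvNTCRun(config=cfg, factors=factors, model=model,
                      mctd_diagnostics=diag, train_log=log,
                      provenance=provenance)


def score_triplets(run: ConvNTCRun, triplets, method: str = "convntc") -> np.ndarray:
    """Score query cells with the full model or the MCTD-only variant.

    "convntc": NTD probabilities; "mctd": raw CP reconstruction values (used
    as ranking scores; they are not squashed).
    """
    triples = np.asarray(list(triplets))
    if method == "convntc":
        return predict_batch(triples, run.model)
    if method == "mctd":
        return score_cells(run.factors, triples)
    raise ValueError(f"unknown scoring method {method!r}")


def derive_pair_scores(scored, mode: str) -> list[tuple[tuple[int, int], float]]:
    """Collapse triplet scores to pairs.

    "AA": pair (i, j) takes the maximum score over contexts k.
    "AB": each triplet contributes pairs (i, k) and (j, k) with its score;
    repeated pairs keep the maximum.
    """
    scored = list(scored)
    if not scored:
        raise ValueError("empty scored list")
    pairs: dict[tuple[int, int], float] = {}

    def keep_max(key, s):
        if key not in pairs or s > pairs[key]:
            pairs[key] = s

    for (i, j, k, s) in scored:
        if mode == "AA":
            keep_max((min(i, j), max(i, j)), s)
        elif mode == "AB":
            keep_max((i, k), s)
            keep_max((j, k), s)
        else:
            raise ValueError(f"mode must be 'AA' or 'AB', got {mode!r}")
    return sorted(pairs.items())


def build_pair_network(scored, top_frac: float = 0.005, aggregate: str = "sum"
                       ) -> list[tuple[int, int, float]]:
    """Aggregate triplet scores over the context axis and keep the top pairs.

    Self-loop pairs (i == j) are removed; pairs are ranked by descending
    aggregate with lexicographic tie-break, and the top ceil(top_frac *
    n_pairs) are returned as (i, j, aggregate) edges.
    """
    scored = list(scored)
    if not scored:
        raise ValueError("empty scored list")
    agg_fns = {"sum": np.sum, "mean": np.mean, "max": np.max}
    if aggregate not in agg_fns:
        raise ValueError(f"aggregate must be one of {sorted(agg_fns)}")
    per_pair: dict[tuple[int, int], list[float]] = {}
    for (i, j, k, s) in scored:
        if i == j:
            continue
        per_pair.setdefault((min(i, j), max(i, j)), []).append(s)
    if not per_pair:
        return []
    edges = [(i, j, float(agg_fns[aggregate](v))) for (i, j), v in per_pair.items()]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    n_keep = int(np.ceil(top_frac * len(edges)))
    return edges[:n_keep]
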