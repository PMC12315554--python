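"""Evaluation harness: metrics, cross-validation splits, robustness grids.

Cross-validation is 5-fold with 5 repetitions by default, either at the
triplet level or at the entity level (cold start: every triplet touching a
held-out entity of the chosen axis goes to the test set).  Negatives are
sampled once per fold-repetition from cells absent from the full dataset, so
no sampled negative can coincide with a held-out positive; leakage is audited
programmatically inside :func:`run_cv`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, average_precision_score

from .data_model import TripletDataset, SimilarityMatrix, build_tensor, candidate_cells
from .mctd import mctd_fit, score_cells
from .pipeline import ConvNTCConfig, run_convntc, score_triplets

__all__ = ["MetricsReport", "SplitSpec", "compute_metrics", "make_splits",
           "run_cv", "robustness_grid", "paired_t_test"]

METRIC_NAMES = ("auprc", "auroc", "f1", "accuracy", "recall", "specificity",
                "precision")


@dataclass
class MetricsReport:
    """The seven ranking/threshold metrics for one scored split."""

    auprc: float
    auroc: float
    f1: float
    accuracy: float
    recall: float
    specificity: float
    precision: float
    n_pos: int
    n_neg: int
    threshold: float

    def as_dict(self) -> dict:
        return asdict(self)


def compute_metrics(scores, labels, threshold: float = 0.5,
                    ranking: bool = True) -> MetricsReport:
    """AUROC/AUPRC plus confusion-matrix metrics at ``threshold``.

    AUROC is the probability that a random positive outranks a random negative
    (ties count 1/2); AUPRC uses step-wise interpolation.  With a single-class
    input the ranking metrics are undefined: an error unless ``ranking`` is
    False, in which case they are reported as NaN.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if min(n_pos, n_neg) == 0:
        if ranking:
            raise ValueError("ranking metrics undefined for single-class input")
        auroc = auprc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, scores))
        auprc = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    recall = tp / n_pos if n_pos else 0.0
    specificity = tn / n_neg if n_neg else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    accuracy = (tp + tn) / len(labels) if len(labels) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return MetricsReport(auprc=auprc, auroc=auroc, f1=f1, accuracy=accuracy,
                         recall=recall, specificity=specificity,
                         precision=precision, n_pos=n_pos, n_neg=n_neg,
                         threshold=threshold)


@dataclass
class SplitSpec:
    """Cross-validation layout: unit of splitting, folds, repetitions, seed."""

    mode: str = "triplet"  # triplet | entity_A | entity_B
    k: int = 5
    reps: int = 5
    seed: int = 0
    val_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("triplet", "entity_A", "entity_B"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("need at least 2 folds")


def _rep_rng(spec: SplitSpec, rep: int, tag: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, rep, tag]))


def make_splits(ds: TripletDataset, spec: SplitSpec
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train_idx, test_idx) pairs, k folds times reps entries.

    Triplet mode partitions the triplet index set; entity modes partition the
    entities of the chosen axis and send every triplet touching a test entity
    to the test side.
    """
    out = []
    for rep in range(spec.reps):
        rng = _rep_rng(spec, rep)
        if spec.mode == "triplet":
            if spec.k > len(ds):
                raise ValueError("more folds than triplets")
            perm = rng.permutation(len(ds))
            folds = np.array_split(perm, spec.k)
            for f in range(spec.k):
                test = np.sort(folds[f])
                train = np.sort(np.concatenate(
                    [folds[g] for g in range(spec.k) if g != f]))
                out.append((train, test))
        else:
            n_ent = ds.n_B if spec.mode == "entity_B" else ds.n_A
            if spec.k > n_ent:
                raise ValueError("more folds than entities")
            perm = rng.permutation(n_ent)
            ent_folds = np.array_split(perm, spec.k)
            for f in range(spec.k):
                held = set(ent_folds[f].tolist())
                if spec.mode == "entity_B":
                    is_test = np.array([k in held for (_, _, k) in ds.triplets])
                else:
                    is_test = np.array([(i in held) or (j in held)
                                        for (i, j, _) in ds.triplets])
                out.append((np.flatnonzero(~is_test), np.flatnonzero(is_test)))
    return out


def _touches_test(cell, held: set, mode: str) -> bool:
    i, j, k = cell
    if mode == "entity_B":
        return k in held
    return (i in held) or (j in held)


def _child_seeds(spec: SplitSpec, rep: int, fold: int) -> np.ndarray:
    ss = np.random.SeedSequence([spec.seed, rep, fold])
    return ss.generate_state(4) % (2 ** 31)


def run_cv(ds: TripletDataset, Sm: SimilarityMatrix, Sd: SimilarityMatrix,
           cfg: ConvNTCConfig, spec: SplitSpec, neg_ratio: float = 1.0,
           train_frac: float = 1.0, method: str = "convntc",
           threshold: float = 0.5, audit: bool = True
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated k-fold cross-validation of the full pipeline.

    Folds split the positive triplets of ``ds`` (or its entities in
    cold-start modes); per fold, negatives are sampled from cells absent from
    the full dataset, the tensor and the NTD training set are built from
    training triplets only, and the held-out positives plus test negatives are
    scored.  ``train_frac`` < 1 retains only floor(train_frac * n) of the
    training positives.  Returns (per-fold table, mean/sd summary).
    """
    pos = ds.subset(np.flatnonzero(ds.labels == 1))
    pool = candidate_cells(ds)  # canonical cells absent from the FULL dataset
    splits = make_splits(pos, spec)
    held_entities: list[set] = []
    if spec.mode != "triplet":
        n_ent = ds.n_B if spec.mode == "entity_B" else ds.n_A
        for rep in range(spec.reps):
            rng = _rep_rng(spec, rep)
            for fold_ids in np.array_split(rng.permutation(n_ent), spec.k):
                held_entities.append(set(fold_ids.tolist()))

    rows = []
    for idx, (train_idx, test_idx) in enumerate(splits):
        rep, fold = divmod(idx, spec.k)
        seeds = _child_seeds(spec, rep, fold)
        rng = np.random.default_rng(seeds[0])

        train_pos = pos.subset(train_idx)
        test_pos = pos.subset(test_idx)
        if train_frac < 1.0:
            keep = int(np.floor(train_frac * len(train_pos)))
            sel = np.sort(rng.choice(len(train_pos), size=keep, replace=False))
            train_pos = train_pos.subset(sel)
        if len(train_pos) == 0 or len(test_pos) == 0:
            continue

        n_tr_neg = int(round(neg_ratio * len(train_pos)))
        n_te_neg = int(round(neg_ratio * len(test_pos)))
        if spec.mode == "triplet":
            chosen = rng.choice(len(pool), size=n_tr_neg + n_te_neg, replace=False)
            train_negs = [pool[c] for c in chosen[:n_tr_neg]]
            test_negs = [pool[c] for c in chosen[n_tr_neg:]]
        else:
            held = held_entities[idx]
            pool_te = [c for c in pool if _touches_test(c, held, spec.mode)]
            pool_tr = [c for c in pool if not _touches_test(c, held, spec.mode)]
            train_negs = [pool_tr[c] for c in
                          rng.choice(len(pool_tr), size=n_tr_neg, replace=False)]
            test_negs = [pool_te[c] for c in
                         rng.choice(len(pool_te), size=n_te_neg, replace=False)]

        train_ds = TripletDataset(
            train_pos.triplets + train_negs,
            np.concatenate([np.ones(len(train_pos), dtype=int),
                            np.zeros(len(train_negs), dtype=int)]),
            ds.n_A, ds.n_B)
        test_triplets = test_pos.triplets + test_negs
        test_labels = np.concatenate([np.ones(len(test_pos), dtype=int),
                                      np.zeros(len(test_negs), dtype=int)])

        if audit:
            train_keys = train_ds.key_set()
            test_keys = set(test_triplets)
            assert train_keys.isdisjoint(test_keys), "train/test leakage"
            X_train = build_tensor(train_ds)
            obs = set(X_train.entries)
            for (i, j, k) in test_keys:
                assert (i, j, k) not in obs and (j, i, k) not in obs, \
                    "test triplet present in observed tensor"
            if spec.mode != "triplet":
                held = held_entities[idx]
                for cell in train_keys:
                    assert not _touches_test(cell, held, spec.mode), \
                        "held-out entity appears in training data"

        cfg_fold = ConvNTCConfig(
            mctd=type(cfg.mctd)(**{**asdict(cfg.mctd), "seed": int(seeds[1])}),
            train=type(cfg.train)(**{**asdict(cfg.train), "seed": int(seeds[2]),
                                     "val_fraction": spec.val_fraction}),
            gamma=cfg.gamma, n_channels=cfg.n_channels, n_grid=cfg.n_grid)

        if method == "mctd":
            factors, _ = mctd_fit(build_tensor(train_ds), Sm, Sd, cfg_fold.mctd)
            scores = score_cells(factors, test_triplets)
        else:
            run = run_convntc(train_ds, Sm, Sd, cfg_fold)
            scores = score_triplets(run, test_triplets, method=method)

        rep_metrics = compute_metrics(scores, test_labels, threshold=threshold)
        rows.append({"rep": rep, "fold": fold, "method": method,
                     **{m: getattr(rep_metrics, m) for m in METRIC_NAMES},
                     "n_pos": rep_metrics.n_pos, "n_neg": rep_metrics.n_neg})

    per_fold = pd.DataFrame(rows)
    summary = per_fold[list(METRIC_NAMES)].agg(["mean", "std"]).T.reset_index()
    summary.columns = ["metric", "mean", "sd"]
    summary["n_folds"] = len(per_fold)
    return per_fold, summary


def robustness_grid(ds: TripletDataset, Sm: SimilarityMatrix,
                    Sd: SimilarityMatrix, cfg: ConvNTCConfig, spec: SplitSpec,
                    neg_ratios=None, train_fracs=None,
                    method: str = "convntc") -> pd.DataFrame:
    """Rerun CV over negative-ratio and training-fraction grids (long format)."""
    records = []
    for ratio in (neg_ratios or []):
        _, summary = run_cv(ds, Sm, Sd, cfg, spec, neg_ratio=ratio, method=method)
        for _, row in summary.iterrows():
            records.append({"setting": "neg_ratio", "value": ratio,
                            "metric": row["metric"], "mean": row["mean"],
                            "sd": row["sd"]})
    for frac in (train_fracs or []):
        _, summary = run_cv(ds, Sm, Sd, cfg, spec, train_frac=frac, method=method)
        for _, row in summary.iterrows():
            records.append({"setting": "train_frac", "value": frac,
                            "metric": row["metric"], "mean": row["mean"],
                            "sd": row["sd"]})
    return pd.DataFrame(records)


def paired_t_test(a, b) -> float:
    """Two-sided paired t-test p-value on fold-wise metric differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 entries")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            warnings.warn("zero variance of differences: exact tie, p = 1.0")
            return 1.0
        return 0.0  # constant nonzero shift, zero noise
    return float(stats.ttest_rel(a, b).pvalue)
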