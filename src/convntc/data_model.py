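"""Domain types and I/O for A-A-B triplet data.

An A-A-B triplet relates two entities of the same type A (miRNAs, drugs) and
one context entity of type B (disease, cell line).  Because the relation is
symmetric in its first two arguments, triplets are stored in *canonical* form
(i <= j) and mirrored only when the third-order tensor is materialised.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TripletDataset",
    "SimilarityMatrix",
    "IncompleteTensor",
    "canonicalize_triplet",
    "load_triplets",
    "write_triplets",
    "binarize_synergy",
    "load_similarity",
    "write_similarity",
    "average_similarities",
    "sample_negatives",
    "build_tensor",
]

_SYM_TOL = 1e-10


def canonicalize_triplet(i: int, j: int, k: int) -> tuple[int, int, int]:
    """Order the two symmetric A-indices so that i <= j."""
    if i < 0 or j < 0 or k < 0:
        raise ValueError(f"negative index in triplet ({i}, {j}, {k})")
    return (i, j, k) if i <= j else (j, i, k)


@dataclass
class TripletDataset:
    """Labeled canonical (i, j, k) triplets over n_A A-entities and n_B B-entities."""

    triplets: list[tuple[int, int, int]]
    labels: np.ndarray
    n_A: int
    n_B: int
    names_A: list[str] | None = None
    names_B: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.triplets):
            raise ValueError("labels and triplets have different lengths")
        seen: set[tuple[int, int, int]] = set()
        for (i, j, k) in self.triplets:
            if i > j:
                raise ValueError(f"non-canonical triplet ({i}, {j}, {k})")
            if i < 0 or j >= self.n_A or k < 0 or k >= self.n_B:
                raise ValueError(f"triplet ({i}, {j}, {k}) out of range "
                                 f"for n_A={self.n_A}, n_B={self.n_B}")
            if (i, j, k) in seen:
                raise ValueError(f"duplicate triplet ({i}, {j}, {k})")
            seen.add((i, j, k))

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == 0))

    def key_set(self) -> set[tuple[int, int, int]]:
        return set(self.triplets)

    def subset(self, idx) -> "TripletDataset":
        idx = np.asarray(idx)
        return TripletDataset(
            [self.triplets[t] for t in idx], self.labels[idx],
            self.n_A, self.n_B, self.names_A, self.names_B,
        )

    def merged_with(self, other: "TripletDataset") -> "TripletDataset":
        if (other.n_A, other.n_B) != (self.n_A, self.n_B):
            raise ValueError("entity counts differ")
        return TripletDataset(
            self.triplets + other.triplets,
            np.concatenate([self.labels, other.labels]),
            self.n_A, self.n_B, self.names_A, self.names_B,
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix (unitless, typically in [0, 1])."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix has non-finite entries")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @staticmethod
    def symmetrized(values: np.ndarray) -> "SimilarityMatrix":
        values = np.asarray(values, dtype=float)
        return SimilarityMatrix(0.5 * (values + values.T))


@dataclass
class IncompleteTensor:
    """Sparse third-order tensor, symmetric in its first two modes.

    A cell is *observed* iff present in ``entries``; both mirror images of an
    off-diagonal cell are stored with equal value.
    """

    dims: tuple[int, int, int]
    entries: dict[tuple[int, int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1, n2, n3 = self.dims
        if n1 != n2:
            raise ValueError("first two dims must be equal")
        for (i, j, k), v in self.entries.items():
            mirror = self.entries.get((j, i, k))
            if mirror is None or mirror != v:
                raise ValueError(f"entry ({i},{j},{k}) lacks an equal mirror image")

    @property
    def n_observed(self) -> int:
        return len(self.entries)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, mask) dense arrays; unobserved cells are 0 / False."""
        X = np.zeros(self.dims)
        O = np.zeros(self.dims, dtype=bool)
        for (i, j, k), v in self.entries.items():
            X[i, j, k] = v
            O[i, j, k] = True
        return X, O


# ---------------------------------------------------------------------------
# file I/O


def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [tok.strip() for tok in line.split(sep)]


def load_triplets(path, score_column: bool = False, threshold: float = 30.0,
                  n_A: int | None = None, n_B: int | None = None,
                  one_based: bool = False) -> TripletDataset:
    """Read a delimited triplet table (columns i, j, k, label-or-score).

    With ``score_column`` the fourth column holds a continuous synergy score
    binarized at ``threshold``; otherwise it holds a {0, 1} label.  A header
    row and '#' comments are skipped; indices may be 1-based (``one_based``).
    Symmetric and exact duplicates collapse; conflicting labels are an error.
    """
    if isinstance(path, io.IOBase):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()

    records: dict[tuple[int, int, int], int] = {}
    max_i = max_k = -1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = _split_row(line)
        if len(toks) < 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(toks)}")
        try:
            i, j, k = int(toks[0]), int(toks[1]), int(toks[2])
            val = float(toks[3])
        except ValueError:
            if lineno == 1:  # optional header
                continue
            raise ValueError(f"line {lineno}: non-numeric field in {toks!r}") from None
        if not np.isfinite(val):
            raise ValueError(f"line {lineno}: non-finite value")
        if one_based:
            i, j, k = i - 1, j - 1, k - 1
        if score_column:
            label = int(binarize_synergy([val], threshold)[0])
        else:
            if val not in (0.0, 1.0):
                raise ValueError(f"line {lineno}: label must be 0 or 1, got {val}")
            label = int(val)
        key = canonicalize_triplet(i, j, k)
        if key in records:
            if records[key] != label:
                raise ValueError(f"line {lineno}: conflicting labels for {key}")
        else:
            records[key] = label
        max_i = max(max_i, key[1])
        max_k = max(max_k, key[2])

    keys = sorted(records)
    labels = np.array([records[key] for key in keys], dtype=int)
    return TripletDataset(
        keys, labels,
        n_A if n_A is not None else max_i + 1,
        n_B if n_B is not None else max_k + 1,
    )


def write_triplets(ds: TripletDataset, path) -> None:
    """Write canonical triplets as TSV (i, j, k, label), sorted, LF endings."""
    order = sorted(range(len(ds)), key=lambda t: ds.triplets[t])
    buf = "".join(
        f"{ds.triplets[t][0]}\t{ds.triplets[t][1]}\t{ds.triplets[t][2]}\t{int(ds.labels[t])}\n"
        for t in order
    )
    if isinstance(path, io.IOBase):
        path.write(buf)
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write(buf)


def binarize_synergy(scores, threshold: float = 30.0) -> np.ndarray:
    """Label 1 iff a continuous synergy score strictly exceeds ``threshold``."""
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("NaN synergy score")
    return (scores > threshold).astype(int)


def load_similarity(path, symmetrize: bool = False) -> SimilarityMatrix:
    """Read a dense square similarity matrix (TSV/CSV, optional id headers)."""
    if isinstance(path, io.IOBase):
        lines = [ln for ln in path.read().splitlines() if ln.strip()]
    else:
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    rows = [_split_row(ln) for ln in lines if not ln.startswith("#")]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if rows and not all(_numeric(t) for t in rows[0]):
        rows = rows[1:]  # header row of column ids
    parsed = []
    for row in rows:
        if row and not _numeric(row[0]):
            row = row[1:]  # leading row id
        parsed.append([float(t) for t in row])
    values = np.array(parsed)
    if symmetrize:
        return SimilarityMatrix.symmetrized(values)
    return SimilarityMatrix(values)


def write_similarity(S: SimilarityMatrix, path) -> None:
    buf = "".join("\t".join(repr(float(v)) for v in row) + "\n" for row in S.values)
    if isinstance(path, io.IOBase):
        path.write(buf)
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write(buf)


# ---------------------------------------------------------------------------
# dataset construction


def average_similarities(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Elementwise arithmetic mean of equally sized similarity matrices."""
    if not mats:
        raise ValueError("need at least one similarity matrix")
    size = mats[0].size
    if any(m.size != size for m in mats):
        raise ValueError("similarity matrices differ in size")
    return SimilarityMatrix(np.mean([m.values for m in mats], axis=0))


def candidate_cells(ds: TripletDataset, include_diagonal: bool = False):
    """Canonical cells (i <= j) absent from the dataset, in lexicographic order."""
    present = ds.key_set()
    out = []
    for i in range(ds.n_A):
        for j in range(i if include_diagonal else i + 1, ds.n_A):
            for k in range(ds.n_B):
                if (i, j, k) not in present:
                    out.append((i, j, k))
    return out


def sample_negatives(ds: TripletDataset, ratio: float = 1.0, seed: int = 0,
                     include_diagonal: bool = False) -> TripletDataset:
    """Augment ``ds`` with round(ratio * n_pos) uniformly sampled label-0 cells.

    Candidates are canonical cells absent from the dataset; self-pairs (i == j)
    are excluded by default.  Deterministic for a fixed seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_draw = int(round(ratio * ds.n_pos))
    pool = candidate_cells(ds, include_diagonal)
    if len(pool) < n_draw:
        raise ValueError(f"only {len(pool)} unobserved cells for {n_draw} negatives")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_draw, replace=False)
    negs = TripletDataset([pool[c] for c in sorted(chosen)],
                          np.zeros(n_draw, dtype=int), ds.n_A, ds.n_B)
    return ds.merged_with(negs)


def build_tensor(ds: TripletDataset) -> IncompleteTensor:
    """Place each canonical triplet at (i, j, k) and its mirror (j, i, k)."""
    entries: dict[tuple[int, int, int], float] = {}
    for (i, j, k), y in zip(ds.triplets, ds.labels):
        entries[(i, j, k)] = float(y)
        entries[(j, i, k)] = float(y)
    return IncompleteTensor((ds.n_A, ds.n_A, ds.n_B), entries)
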