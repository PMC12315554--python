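"""Multi-constraint tensor decomposition (MCTD) solved by ADMM.

The multilinear stage factorizes a third-order tensor, symmetric in its first
two modes, as a CP/INDSCAL model [[M, C, D]] while constraining the factors
with (i) similarity reconstruction terms ||S_A - M A_m M^T||_F^2 and
||S_B - D A_d D^T||_F^2, (ii) graph-Laplacian smoothness tr(M^T U M),
tr(D^T V D), and (iii) a column-sparsity (L2,1-type) penalty.  Consensus
copies C = Z = H = M and P = F = D decouple the constraints; each block then
has a closed-form update of the augmented Lagrangian, the r x r projection
matrices A_m, A_d are updated by conjugate gradients, and unobserved tensor
cells are imputed from the current model between sweeps (EM-style).

The column-sparsity penalty enters the M and D updates through a diagonal
weight W with W(k,k) = 0.5 * ||column k||_2, treated as a frozen-weight
(iteratively reweighted) quadratic surrogate: weights are recomputed from the
incoming block before each update, so every block update is the exact
minimizer of :func:`augmented_lagrangian` with those weights held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import IncompleteTensor, SimilarityMatrix

__all__ = [
    "MCTDHyperparams",
    "FactorSet",
    "ADMMState",
    "laplacian",
    "matricize",
    "khatri_rao",
    "reconstruct_cp",
    "row_weight",
    "block_update",
    "update_multipliers",
    "cg_solve_projection",
    "impute",
    "augmented_lagrangian",
    "init_state",
    "mctd_fit",
]

PENALTY_CAP = 1e8


@dataclass
class MCTDHyperparams:
    """Rank, constraint weights, ADMM penalties and stopping rules.

    mu/eta weight the A- and B-side similarity constraints, alpha/beta the
    Laplacian smoothness terms, lam the column-sparsity + projection ridge.
    rho1..3, theta1..2 are initial consensus penalties, multiplied by
    eps_scale (default 1.15) after every sweep up to PENALTY_CAP.
    """

    r: int = 4
    mu: float = 0.1
    eta: float = 0.1
    alpha: float = 0.1
    beta: float = 0.1
    lam: float = 0.1
    rho1: float = 1.0
    rho2: float = 1.0
    rho3: float = 1.0
    theta1: float = 1.0
    theta2: float = 1.0
    eps_scale: float = 1.15
    max_iters: int = 300
    tol: float = 1e-5
    cg_iters: int = 50
    cg_tol: float = 1e-10
    l21_convention: str = "printed"  # or "standard": 1 / (2 ||col|| + 1e-12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("rank must be >= 1")
        if min(self.rho1, self.rho2, self.rho3, self.theta1, self.theta2) <= 0:
            raise ValueError("penalties must be positive")
        if self.eps_scale < 1:
            raise ValueError("eps_scale must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FactorSet:
    """Fitted factor matrices M, C (both n_A x r), D (n_B x r) and projections."""

    M: np.ndarray
    C: np.ndarray
    D: np.ndarray
    A_m: np.ndarray
    A_d: np.ndarray

    @property
    def rank(self) -> int:
        return self.M.shape[1]


@dataclass
class ADMMState:
    factors: FactorSet
    H: np.ndarray
    Z: np.ndarray
    P: np.ndarray
    F: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray
    Y3: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    rho1: float
    rho2: float
    rho3: float
    theta1: float
    theta2: float
    X_hat: np.ndarray
    U: np.ndarray
    V: np.ndarray
    iter: int = 0


# ---------------------------------------------------------------------------
# tensor primitives


def laplacian(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Graph Laplacian Deg - S; symmetric with zero row sums."""
    A = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("Laplacian needs a square matrix")
    return np.diag(A.sum(axis=1)) - A


def matricize(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding with the fiber ordering matching :func:`khatri_rao`.

    The convention is fixed so that for T = [[M, C, D]]:
    T_(1) = M kr(C, D)^T, T_(2) = C kr(M, D)^T, T_(3) = D kr(M, C)^T.
    """
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError("expected a 3-way array")
    if mode == 1:
        return X.reshape(X.shape[0], -1)
    if mode == 2:
        return np.moveaxis(X, 1, 0).reshape(X.shape[1], -1)
    if mode == 3:
        return np.moveaxis(X, 2, 0).reshape(X.shape[2], -1)
    raise ValueError(f"mode must be 1, 2 or 3, got {mode}")


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product; row (a, b) is a-major."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError("column counts differ")
    return (A[:, None, :] * B[None, :, :]).reshape(A.shape[0] * B.shape[0], -1)


def reconstruct_cp(M: np.ndarray, C: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Dense [[M, C, D]]: entry (i, j, k) = sum_l M_il C_jl D_kl."""
    if not (M.shape[1] == C.shape[1] == D.shape[1]):
        raise ValueError("factor ranks differ")
    return np.einsum("il,jl,kl->ijk", M, C, D)


def row_weight(Mat: np.ndarray, convention: str = "printed") -> np.ndarray:
    """Diagonal column-sparsity weights for the reweighted quadratic surrogate.

    "printed": W(k,k) = 0.5 ||col k||_2; "standard": the classical L2,1
    majorization weight 1 / (2 ||col k||_2 + 1e-12).
    """
    norms = np.linalg.norm(Mat, axis=0)
    if convention == "printed":
        return np.diag(0.5 * norms)
    if convention == "standard":
        return np.diag(1.0 / (2.0 * norms + 1e-12))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# block updates


def _solve_right(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Return num @ den^{-1} for symmetric positive-definite den."""
    try:
        out = np.linalg.solve(den, num.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular block system; increase the ADMM penalties (all must be > 0)"
        ) from exc
    return out


def block_update(block: str, state: ADMMState, hp: MCTDHyperparams,
                 Sm: SimilarityMatrix, Sd: SimilarityMatrix) -> np.ndarray:
    """Closed-form minimizer of the augmented Lagrangian w.r.t. one block.

    Blocks: M, C, H, Z (A-side) and D, P, F (B-side).  All other blocks and
    the imputed tensor in ``state`` stay fixed.  For M and D the sparsity
    weights are frozen at the incoming block value.
    """
    f = state.factors
    M, C, D, Am, Ad = f.M, f.C, f.D, f.A_m, f.A_d
    Sm_v, Sd_v = Sm.values, Sd.values
    r = hp.r
    I = np.eye(r)

    if block == "M":
        E = khatri_rao(C, D)
        X1 = matricize(state.X_hat, 1)
        W = row_weight(M, hp.l21_convention)
        num = (X1 @ E + hp.mu * Sm_v @ state.H @ Am.T
               + state.rho1 * C + state.theta1 * state.H + state.rho2 * state.Z
               - state.Y1 - state.R1 - state.Y2)
        den = (E.T @ E + hp.mu * Am @ state.H.T @ state.H @ Am.T
               + 0.5 * hp.lam * W
               + (state.rho1 + state.theta1 + state.rho2) * I)
        return _solve_right(num, den)
    if block == "C":
        G = khatri_rao(M, D)
        X2 = matricize(state.X_hat, 2)
        return _solve_right(X2 @ G + state.rho1 * M + state.Y1,
                            G.T @ G + state.rho1 * I)
    if block == "H":
        # exact minimizer; coincides with the A_m-symmetric closed form
        num = hp.mu * Sm_v.T @ M @ Am + state.theta1 * M + state.R1
        den = hp.mu * Am.T @ (M.T @ M) @ Am + state.theta1 * I
        return _solve_right(num, den)
    if block == "Z":
        A = hp.alpha * state.U + state.rho2 * np.eye(state.U.shape[0])
        return np.linalg.solve(A, state.rho2 * M + state.Y2)
    if block == "D":
        J = khatri_rao(M, C)
        X3 = matricize(state.X_hat, 3)
        W = row_weight(D, hp.l21_convention)
        num = (X3 @ J + hp.eta * Sd_v @ state.P @ Ad.T
               + state.theta2 * state.P + state.rho3 * state.F
               - state.R2 - state.Y3)
        den = (J.T @ J + hp.eta * Ad @ state.P.T @ state.P @ Ad.T
               + 0.5 * hp.lam * W
               + (state.theta2 + state.rho3) * I)
        return _solve_right(num, den)
    if block == "P":
        num = hp.eta * Sd_v.T @ D @ Ad + state.theta2 * D + state.R2
        den = hp.eta * Ad.T @ (D.T @ D) @ Ad + state.theta2 * I
        return _solve_right(num, den)
    if block == "F":
        A = hp.beta * state.V + state.rho3 * np.eye(state.V.shape[0])
        return np.linalg.solve(A, state.rho3 * D + state.Y3)
    raise ValueError(f"unknown block {block!r}")


def update_multipliers(state: ADMMState, hp: MCTDHyperparams) -> ADMMState:
    """Dual ascent on all five multipliers, then geometric penalty growth."""
    f = state.factors
    state.Y1 = state.Y1 + state.rho1 * (f.M - f.C)
    state.Y2 = state.Y2 + state.rho2 * (f.M - state.Z)
    state.Y3 = state.Y3 + state.rho3 * (f.D - state.F)
    state.R1 = state.R1 + state.theta1 * (f.M - state.H)
    state.R2 = state.R2 + state.theta2 * (f.D - state.P)
    e = hp.eps_scale
    state.rho1 = min(state.rho1 * e, PENALTY_CAP)
    state.rho2 = min(state.rho2 * e, PENALTY_CAP)
    state.rho3 = min(state.rho3 * e, PENALTY_CAP)
    state.theta1 = min(state.theta1 * e, PENALTY_CAP)
    state.theta2 = min(state.theta2 * e, PENALTY_CAP)
    return state


def cg_solve_projection(S: SimilarityMatrix | np.ndarray, M: np.ndarray,
                        mu: float, lam: float,
                        iters: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Conjugate-gradient solve for the r x r projection matrix A.

    Minimizes (mu/2)||S - M A M^T||_F^2 + (lam/2)||A||_F^2, i.e. solves the
    linear system mu M^T M A M^T M + lam A = mu M^T S M, starting from A = 0.
    """
    S_v = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if mu < 0 or lam < 0 or (mu == 0 and lam == 0):
        raise ValueError("mu, lam must be >= 0 and not both 0")
    MtM = M.T @ M

    def op(B: np.ndarray) -> np.ndarray:
        return mu * MtM @ B @ MtM + lam * B

    A = np.zeros((M.shape[1], M.shape[1]))
    R = mu * M.T @ S_v @ M - op(A)
    B = R.copy()
    for _ in range(iters):
        r2 = float(np.sum(R * R))
        if np.sqrt(r2) <= tol:
            break
        denom = mu * np.linalg.norm(M @ B @ M.T) ** 2 + lam * np.linalg.norm(B) ** 2
        if denom == 0.0:
            break
        a = r2 / denom
        A = A + a * B
        R_next = R - a * op(B)
        if not np.all(np.isfinite(R_next)):
            raise FloatingPointError("conjugate-gradient recursion diverged")
        b = float(np.sum(R_next * R_next)) / r2
        B = R_next + b * B
        R = R_next
    return A


def impute(X_obs: IncompleteTensor | tuple[np.ndarray, np.ndarray],
           factors: FactorSet) -> np.ndarray:
    """Fill unobserved cells with model predictions, keep observed values."""
    if isinstance(X_obs, IncompleteTensor):
        X, O = X_obs.to_dense()
    else:
        X, O = X_obs
    X_pre = reconstruct_cp(factors.M, factors.C, factors.D)
    return np.where(O, X, X_pre)


# ---------------------------------------------------------------------------
# objective


def augmented_lagrangian(state: ADMMState, hp: MCTDHyperparams,
                         Sm: SimilarityMatrix, Sd: SimilarityMatrix,
                         W_m: np.ndarray | None = None,
                         W_d: np.ndarray | None = None,
                         overrides: dict[str, np.ndarray] | None = None) -> float:
    """Augmented Lagrangian value at the current (or overridden) blocks.

    The data term carries a 1/2 so that every :func:`block_update` is its
    exact minimizer.  The column-sparsity term uses the frozen diagonal
    weights W_m, W_d (defaulting to weights recomputed from the current M, D),
    entering as (lam/4) tr(M W_m M^T) + (lam/4) tr(D W_d D^T).
    """
    f = state.factors
    blocks = {"M": f.M, "C": f.C, "D": f.D, "H": state.H, "Z": state.Z,
              "P": state.P, "F": state.F, "A_m": f.A_m, "A_d": f.A_d}
    if overrides:
        blocks = {**blocks, **overrides}
    M, C, D = blocks["M"], blocks["C"], blocks["D"]
    H, Z, P, F = blocks["H"], blocks["Z"], blocks["P"], blocks["F"]
    Am, Ad = blocks["A_m"], blocks["A_d"]
    if W_m is None:
        W_m = row_weight(M, hp.l21_convention)
    if W_d is None:
        W_d = row_weight(D, hp.l21_convention)
    sq = lambda A: float(np.sum(A * A))

    val = 0.5 * sq(state.X_hat - reconstruct_cp(M, C, D))
    val += 0.5 * state.rho1 * sq(M - C + state.Y1 / state.rho1)
    val += 0.5 * hp.mu * sq(Sm.values - M @ Am @ H.T)
    val += 0.5 * state.theta1 * sq(M - H + state.R1 / state.theta1)
    val += 0.5 * hp.alpha * float(np.trace(Z.T @ state.U @ Z))
    val += 0.5 * state.rho2 * sq(M - Z + state.Y2 / state.rho2)
    val += 0.5 * hp.eta * sq(Sd.values - D @ Ad @ P.T)
    val += 0.5 * state.theta2 * sq(D - P + state.R2 / state.theta2)
    val += 0.5 * hp.beta * float(np.trace(F.T @ state.V @ F))
    val += 0.5 * state.rho3 * sq(D - F + state.Y3 / state.rho3)
    val += 0.25 * hp.lam * (float(np.trace(M @ W_m @ M.T))
                            + float(np.trace(D @ W_d @ D.T)))
    val += 0.5 * hp.lam * (sq(Am) + sq(Ad))
    return val


# ---------------------------------------------------------------------------
# full solver


def init_state(X_obs: IncompleteTensor, Sm: SimilarityMatrix,
               Sd: SimilarityMatrix, hp: MCTDHyperparams) -> ADMMState:
    """Seeded consensus-consistent start: C=Z=H=M, P=F=D, zero multipliers."""
    n_A, _, n_B = X_obs.dims
    if Sm.size != n_A or Sd.size != n_B:
        raise ValueError("similarity matrix sizes do not match tensor dims")
    rng = np.random.default_rng(hp.seed)
    M = 0.1 * rng.uniform(size=(n_A, hp.r))
    D = 0.1 * rng.uniform(size=(n_B, hp.r))
    X, O = X_obs.to_dense()
    zeros_A = np.zeros((n_A, hp.r))
    zeros_B = np.zeros((n_B, hp.r))
    return ADMMState(
        factors=FactorSet(M=M, C=M.copy(), D=D,
                          A_m=np.zeros((hp.r, hp.r)), A_d=np.zeros((hp.r, hp.r))),
        H=M.copy(), Z=M.copy(), P=D.copy(), F=D.copy(),
        Y1=zeros_A.copy(), Y2=zeros_A.copy(), Y3=zeros_B.copy(),
        R1=zeros_A.copy(), R2=zeros_B.copy(),
        rho1=hp.rho1, rho2=hp.rho2, rho3=hp.rho3,
        theta1=hp.theta1, theta2=hp.theta2,
        X_hat=X,  # first sweep sees unobserved cells as 0
        U=laplacian(Sm), V=laplacian(Sd),
    )


def mctd_fit(X_obs: IncompleteTensor, Sm: SimilarityMatrix,
             Sd: SimilarityMatrix, hp: MCTDHyperparams
             ) -> tuple[FactorSet, dict]:
    """Run the ADMM sweeps until the observed-cell error stabilizes.

    Per sweep: M, C, H, Z updates, then D, P, F, then multipliers and penalty
    growth, then CG updates of A_m, A_d, then imputation of the dense tensor.
    Diagnostics record the objective, observed-cell relative error and the
    five consensus residual norms per sweep.
    """
    X, O = X_obs.to_dense()
    obs_norm = np.linalg.norm(X[O]) if O.any() else 0.0
    state = init_state(X_obs, Sm, Sd, hp)
    diag: dict = {"objective": [], "obs_rel_error": [],
                  "residuals": {"M-C": [], "M-H": [], "M-Z": [], "D-P": [], "D-F": []}}
    prev_err = np.inf
    for it in range(hp.max_iters):
        state.iter = it + 1
        f = state.factors
        f.M = block_update("M", state, hp, Sm, Sd)
        f.C = block_update("C", state, hp, Sm, Sd)
        state.H = block_update("H", state, hp, Sm, Sd)
        state.Z = block_update("Z", state, hp, Sm, Sd)
        f.D = block_update("D", state, hp, Sm, Sd)
        state.P = block_update("P", state, hp, Sm, Sd)
        state.F = block_update("F", state, hp, Sm, Sd)
        state = update_multipliers(state, hp)
        f.A_m = cg_solve_projection(Sm, f.M, hp.mu, hp.lam, hp.cg_iters, hp.cg_tol)
        f.A_d = cg_solve_projection(Sd, f.D, hp.eta, hp.lam, hp.cg_iters, hp.cg_tol)

        X_pre = reconstruct_cp(f.M, f.C, f.D)
        state.X_hat = np.where(O, X, X_pre)

        if O.any() and obs_norm > 0:
            err = np.linalg.norm((X_pre - X)[O]) / obs_norm
        else:
            err = 0.0
        obj = augmented_lagrangian(state, hp, Sm, Sd)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at iteration {it + 1}; diagnostics: {diag}")
        diag["objective"].append(obj)
        diag["obs_rel_error"].append(err)
        diag["residuals"]["M-C"].append(np.linalg.norm(f.M - f.C))
        diag["residuals"]["M-H"].append(np.linalg.norm(f.M - state.H))
        diag["residuals"]["M-Z"].append(np.linalg.norm(f.M - state.Z))
        diag["residuals"]["D-P"].append(np.linalg.norm(f.D - state.P))
        diag["residuals"]["D-F"].append(np.linalg.norm(f.D - state.F))

        if np.isfinite(prev_err) and abs(prev_err - err) / max(prev_err, 1e-12) < hp.tol:
            break
        prev_err = err
    diag["n_iters"] = state.iter
    return state.factors, diag


def score_cells(factors: FactorSet, triplets) -> np.ndarray:
    """Model reconstruction [[M, C, D]] evaluated at query cells."""
    idx = np.asarray(list(triplets))
    return np.einsum("tl,tl,tl->t", factors.M[idx[:, 0]],
                     factors.C[idx[:, 1]], factors.D[idx[:, 2]])
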