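"""Cross-validated ridge biological-age clocks.

A clock maps one preprocessed omics panel to predicted age.  Training follows
the stepped-inclusion scheme: the sample is split into K folds; within each
training set markers are ranked by their absolute correlation with age and
the top-k enter a ridge regression (penalty chosen by nested cross-validation)
whose predictions on the held-out fold are *out-of-fold* biological ages.
The candidate count k is selected globally by a plateau rule on the
out-of-fold validation curve: the smallest candidate whose correlation with
age is within a tolerance of the best.  For small targeted panels the
candidate list is simply "all markers".

The ridge solver is written in closed form (eigendecomposition of the normal
or Gram matrix, whichever is smaller) so the whole penalty path costs one
factorization per fold.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OmicsLayer
from .config import InputError

__all__ = [
    "ClockFit",
    "make_folds",
    "rank_markers_by_age",
    "fit_ridge_age_model",
    "select_step_count",
    "crossval_predict_age",
    "lambda_grid",
]


def make_folds(n: int, K: int, seed: int = 0) -> np.ndarray:
    """Random partition of ``n`` subjects into ``K`` folds (labels 1..K).

    Fold sizes differ by at most one; deterministic given the seed.
    """
    if K < 2:
        raise InputError(f"need at least 2 folds, got K={K}")
    if n < K:
        raise InputError(f"cannot split n={n} subjects into K={K} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(perm, K), start=1):
        assignment[part] = f
    return assignment


def rank_markers_by_age(
    train_matrix: np.ndarray, train_age: np.ndarray
) -> np.ndarray:
    """Column indices sorted by decreasing |Pearson r| with age.

    Constant markers get r = 0 (ranked last); exact ties keep the original
    marker order (stable sort).
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_age, dtype=float)
    if X.shape[0] < 3:
        raise InputError("marker ranking needs at least 3 training subjects")
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("marker ranking requires complete data")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.argsort(-np.abs(r), kind="stable")


def lambda_grid(p: int, n: int, n_lambdas: int = 8) -> np.ndarray:
    """Log-spaced ridge penalty grid, 1e-3..1e4 scaled by p/n.

    The top decade matters for standardized panels dominated by weak signal,
    where the CV-optimal penalty routinely exceeds p/n * 1e3.
    """
    return np.logspace(-3, 4, n_lambdas) * max(p, 1) / max(n, 1)


def fit_ridge_age_model(
    train_matrix: np.ndarray, train_age: np.ndarray, penalty: float
) -> tuple[float, np.ndarray]:
    """Closed-form ridge with an unpenalized intercept.

    Minimizes ``sum (y - b0 - X beta)^2 + penalty * ||beta||^2`` via centering;
    ``penalty=0`` falls back to (minimum-norm) least squares.  Returns
    ``(intercept, coefficients)``.
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_age, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("ridge fit requires complete data")
    if penalty < 0:
        raise InputError(f"ridge penalty must be >= 0, got {penalty}")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    n, p = Xc.shape
    if penalty == 0:
        # minimum-norm least squares when X is rank deficient
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    elif p <= n:
        A = Xc.T @ Xc + penalty * np.eye(p)
        beta = np.linalg.solve(A, Xc.T @ yc)
    else:
        G = Xc @ Xc.T + penalty * np.eye(n)
        beta = Xc.T @ np.linalg.solve(G, yc)
    return float(ym - xm @ beta), beta


def select_step_count(
    candidate_counts, validation_curve, tol: float = 0.01
) -> int:
    """Plateau rule: smallest candidate within ``tol`` of the curve maximum."""
    counts = list(candidate_counts)
    curve = list(validation_curve)
    if not counts:
        raise InputError("candidate list is empty")
    if len(counts) != len(curve):
        raise InputError("candidates and validation curve differ in length")
    if tol < 0:
        raise InputError("tol must be >= 0")
    best = max(curve)
    order = np.argsort(counts, kind="stable")
    for i in order:
        if curve[i] >= best - tol:
            return counts[i]
    return counts[int(order[-1])]  # unreachable; max always qualifies


# ---------------------------------------------------------------------------
# fast penalty-path solvers
# ---------------------------------------------------------------------------

def _primal_path(Xtr, ytr, Xval, lambdas):
    """Validation predictions for every lambda via eigh of X'X (p <= n path)."""
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    Xc = Xtr - xm
    yc = ytr - ym
    w, V = np.linalg.eigh(Xc.T @ Xc)
    w = np.clip(w, 0.0, None)
    proj = V.T @ (Xc.T @ yc)
    coefs = V @ (proj[:, None] / (w[:, None] + lambdas[None, :]))
    return (Xval - xm) @ coefs + ym


class _DualGram:
    """Dual (kernel) ridge over a precomputed Gram matrix of all subjects.

    Centering w.r.t. any training subset is carried out in Gram algebra, so
    inner-CV penalty paths cost one small eigendecomposition per split with
    no access to the marker matrix.
    """

    def __init__(self, G: np.ndarray, y: np.ndarray):
        self.G = G
        self.y = y

    def _centered_blocks(self, train, rows):
        colmean = self.G[:, train].mean(axis=1)  # for every row i: mean_t G[i,t]
        mm = colmean[train].mean()
        blk = (
            self.G[np.ix_(rows, train)]
            - colmean[rows][:, None]
            - colmean[train][None, :]
            + mm
        )
        return blk

    def path_predict(self, train, val, lambdas):
        Gc_tt = self._centered_blocks(train, train)
        w, Q = np.linalg.eigh(Gc_tt)
        w = np.clip(w, 0.0, None)
        ym = self.y[train].mean()
        yc = self.y[train] - ym
        proj = Q.T @ yc
        alphas = Q @ (proj[:, None] / (w[:, None] + lambdas[None, :]))
        Gc_vt = self._centered_blocks(train, val)
        return Gc_vt @ alphas + ym


def _choose_lambda(path_predict, train_idx, age, lambdas, n_inner, seed):
    """Inner K-fold CV over the penalty grid, minimizing validation MSE."""
    m = len(train_idx)
    k_inner = min(n_inner, m)
    inner = make_folds(m, k_inner, seed)
    sse = np.zeros(len(lambdas))
    for g in range(1, k_inner + 1):
        tr = train_idx[inner != g]
        val = train_idx[inner == g]
        preds = path_predict(tr, val, lambdas)
        sse += ((preds - age[val][:, None]) ** 2).sum(axis=0)
    return int(np.argmin(sse))


# ---------------------------------------------------------------------------
# the outer cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClockFit:
    """Result of cross-validated clock training on one layer."""

    layer: str
    n_folds: int
    seed: int
    fold_assignment: np.ndarray
    candidates: list[int]
    validation_curve: list[float]
    k_star: int
    oof_predictions: pd.Series  # out-of-fold predicted biological age (years)
    fold_models: list[dict] = field(default_factory=list)
    marker_names: list[str] | None = None

    def to_json(self, path: str | Path, include_coefficients: bool = False) -> None:
        d = {
            "layer": self.layer,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment.tolist(),
            "candidates": list(self.candidates),
            "validation_curve": [float(v) for v in self.validation_curve],
            "k_star": int(self.k_star),
            "subjects": self.oof_predictions.index.tolist(),
            "oof_predictions": self.oof_predictions.tolist(),
            "fold_models": [
                {
                    "fold": m["fold"],
                    "lambda": m["lambda"],
                    "intercept": m["intercept"],
                    "n_markers": len(m["markers"]),
                    **(
                        {
                            "markers": list(m["markers"]),
                            "coefficients": np.asarray(m["coefficients"]).tolist(),
                        }
                        if include_coefficients
                        else {}
                    ),
                }
                for m in self.fold_models
            ],
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def crossval_predict_age(
    layer: OmicsLayer | pd.DataFrame | np.ndarray,
    age: np.ndarray | pd.Series,
    K: int = 10,
    candidates: list[int] | None = None,
    plateau_tol: float = 0.01,
    n_inner: int = 5,
    n_lambdas: int = 8,
    seed: int = 0,
    store_coefficients: bool = True,
) -> ClockFit:
    """Train a biological-age clock with K-fold CV and stepped marker inclusion.

    For every fold, markers are ranked on the training rows only, the top-k
    (per candidate k) enter a ridge whose penalty is chosen by inner CV on the
    training rows, and predictions are made for the held-out fold — no
    held-out information enters ranking, penalty selection, or fitting.  The
    candidate k* is the smallest count whose out-of-fold correlation with age
    is within ``plateau_tol`` of the best candidate; candidate 0 means an
    intercept-only baseline (predict the training mean age).
    """
    if isinstance(layer, OmicsLayer):
        name = layer.name
        values = layer.values
        if layer.mask is not None and layer.mask.to_numpy().any():
            raise InputError(f"layer {name!r} has missing entries; preprocess first")
    elif isinstance(layer, pd.DataFrame):
        name = "layer"
        values = layer
    else:
        name = "layer"
        values = pd.DataFrame(np.asarray(layer, dtype=float))
    X = values.to_numpy(dtype=float)
    marker_names = [str(c) for c in values.columns]
    if isinstance(age, pd.Series):
        age = age.loc[values.index] if values.index.isin(age.index).all() else age
        y = age.to_numpy(dtype=float)
    else:
        y = np.asarray(age, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise InputError("age vector length does not match the marker matrix")
    if np.isnan(X).any() or np.isnan(y).any():
        raise InputError("clock training requires complete data")

    if candidates is None:
        cand = [p]
    else:
        cand = []
        for k in candidates:
            if k > p:
                warnings.warn(
                    f"candidate count {k} exceeds marker count {p}; clipped",
                    stacklevel=2,
                )
                k = p
            if k not in cand:
                cand.append(int(k))
        cand = sorted(cand)
    folds = make_folds(n, K, seed)

    # per-fold ranking and inner-CV seeds are fixed across candidates
    ss = np.random.SeedSequence(seed)
    inner_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(K)]
    fold_rank: list[np.ndarray] = []
    fold_train: list[np.ndarray] = []
    fold_test: list[np.ndarray] = []
    for f in range(1, K + 1):
        te = np.where(folds == f)[0]
        tr = np.where(folds != f)[0]
        fold_train.append(tr)
        fold_test.append(te)
        fold_rank.append(rank_markers_by_age(X[tr], y[tr]))

    # a full-panel candidate can reuse one Gram matrix across all folds
    full_gram = None
    if p in cand and p > min(len(tr) for tr in fold_train):
        full_gram = _DualGram(X @ X.T, y)

    curve: list[float] = []
    oof_by_cand: dict[int, np.ndarray] = {}
    lam_by_cand: dict[int, list[float]] = {}
    for k in cand:
        oof = np.empty(n)
        lams: list[float] = []
        for f in range(K):
            tr, te = fold_train[f], fold_test[f]
            if k == 0:
                oof[te] = y[tr].mean()
                lams.append(0.0)
                continue
            sel = fold_rank[f][:k]
            grid = lambda_grid(k, len(tr), n_lambdas)
            if k == p and full_gram is not None:
                best = _choose_lambda(
                    full_gram.path_predict, tr, y, grid, n_inner, inner_seeds[f]
                )
                lam = grid[best]
                oof[te] = full_gram.path_predict(tr, te, np.array([lam]))[:, 0]
            elif k > len(tr):
                Xs = X[:, sel]
                dual = _DualGram(Xs @ Xs.T, y)
                best = _choose_lambda(
                    dual.path_predict, tr, y, grid, n_inner, inner_seeds[f]
                )
                lam = grid[best]
                oof[te] = dual.path_predict(tr, te, np.array([lam]))[:, 0]
            else:
                Xs = X[:, sel]

                def path(tr_, val_, lambdas_, Xs=Xs):
                    return _primal_path(Xs[tr_], y[tr_], Xs[val_], lambdas_)

                best = _choose_lambda(path, tr, y, grid, n_inner, inner_seeds[f])
                lam = grid[best]
                oof[te] = path(tr, te, np.array([lam]))[:, 0]
            lams.append(float(lam))
        oof_by_cand[k] = oof
        lam_by_cand[k] = lams
        curve.append(_safe_corr(oof, y))

    k_star = select_step_count(cand, curve, plateau_tol)
    oof = oof_by_cand[k_star]

    fold_models = []
    for f in range(K):
        tr = fold_train[f]
        if k_star == 0:
            fold_models.append(
                {
                    "fold": f + 1,
                    "lambda": 0.0,
                    "intercept": float(y[tr].mean()),
                    "markers": [],
                    "coefficients": np.zeros(0),
                }
            )
            continue
        sel = fold_rank[f][:k_star]
        lam = lam_by_cand[k_star][f]
        intercept, coef = fit_ridge_age_model(X[tr][:, sel], y[tr], lam)
        fold_models.append(
            {
                "fold": f + 1,
                "lambda": lam,
                "intercept": intercept,
                "markers": [marker_names[j] for j in sel],
                "coefficients": coef if store_coefficients else np.zeros(0),
            }
        )

    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(n)
    return ClockFit(
        layer=name,
        n_folds=K,
        seed=int(seed),
        fold_assignment=folds,
        candidates=cand,
        validation_curve=curve,
        k_star=int(k_star),
        oof_predictions=pd.Series(oof, index=index, name=f"{name}_predicted_age"),
        fold_models=fold_models,
        marker_names=marker_names,
    )
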