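"""Drug-target interaction prediction by inductive matrix completion.

Two stages:

1. A denoising autoencoder embeds drug and target side-information rows
   (typically rows of drug-drug / target-target similarity matrices) into
   a low-dimensional space.  Training minimizes the reconstruction error
   of masking-corrupted inputs plus an L2 weight penalty.

2. A biased positive-unlabeled inductive matrix completion (IMC) model
   factorizes the binary interaction matrix ``P`` through the side
   features: ``Score(i, j) = x_i W H^T y_j^T`` with low-rank factors
   ``W`` (f_d x k) and ``H`` (f_t x k).  Observed interactions carry unit
   weight; all unobserved entries are treated as negatives down-weighted
   by ``alpha``.  The objective

       sum_{P_ij = 1} (1 - x_i W H^T y_j^T)^2
       + alpha * sum_{P_ij = 0} (x_i W H^T y_j^T)^2
       + lam * (||W||_F^2 + ||H||_F^2)

   is minimized by alternating least squares: with one factor fixed the
   other solves a ridge-regularized weighted linear system in closed form,
   so the objective is non-increasing across iterations.

Higher scores mean a higher likelihood that drug i interacts with target j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthdata import DrugTargetData


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class AutoencoderModel:
    """Single-hidden-layer denoising autoencoder (sigmoid activations)."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    corruption_rate: float
    embedding_dim: int
    loss_trace: list[float] = field(default_factory=list)


def train_autoencoder(
    features: np.ndarray,
    embedding_dim: int,
    corruption_rate: float = 0.2,
    lam: float = 1e-4,
    epochs: int = 200,
    learning_rate: float = 0.5,
    batch_size: int = 16,
    linear: bool = False,
    seed: int = 0,
) -> AutoencoderModel:
    """Fit the autoencoder by mini-batch gradient descent.

    Inputs are expected scaled to [0, 1].  Masking corruption zeroes a
    ``corruption_rate`` fraction of input entries per presentation; the
    loss is mean squared reconstruction error of the clean input plus
    ``lam`` times the squared Frobenius norm of the weights.
    ``linear=True`` drops the nonlinearities (useful for identity checks).
    """
    X = np.asarray(features, dtype=float)
    n, d = X.shape
    if embedding_dim > d:
        raise ValueError("embedding_dim must not exceed the input width")
    if not 0.0 <= corruption_rate < 1.0:
        raise ValueError("corruption_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(d)
    W1 = rng.uniform(-scale, scale, size=(d, embedding_dim))
    b1 = np.zeros(embedding_dim)
    W2 = rng.uniform(-scale, scale, size=(embedding_dim, d))
    b2 = np.zeros(d)

    def act(z):
        return z if linear else _sigmoid(z)

    def act_grad(a):
        return np.ones_like(a) if linear else a * (1.0 - a)

    trace: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = X[order[start : start + batch_size]]
            m = batch.shape[0]
            mask = (rng.random(batch.shape) >= corruption_rate).astype(float)
            corrupted = batch * mask
            h = act(corrupted @ W1 + b1)
            out = act(h @ W2 + b2)
            err = out - batch
            loss = float((err**2).sum() / m + lam * ((W1**2).sum() + (W2**2).sum()))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite autoencoder loss at epoch {epoch}")
            epoch_loss += loss * m
            d_out = 2.0 * err * act_grad(out) / m
            g_W2 = h.T @ d_out + 2.0 * lam * W2
            g_b2 = d_out.sum(axis=0)
            d_h = d_out @ W2.T * act_grad(h)
            g_W1 = corrupted.T @ d_h + 2.0 * lam * W1
            g_b1 = d_h.sum(axis=0)
            W1 -= learning_rate * g_W1
            b1 -= learning_rate * g_b1
            W2 -= learning_rate * g_W2
            b2 -= learning_rate * g_b2
        trace.append(epoch_loss / n)
    return AutoencoderModel(
        W_enc=W1,
        b_enc=b1,
        W_dec=W2,
        b_dec=b2,
        corruption_rate=corruption_rate,
        embedding_dim=embedding_dim,
        loss_trace=trace,
    )


def embed(model: AutoencoderModel, features: np.ndarray, linear: bool = False) -> np.ndarray:
    """Middle-layer activations of the trained autoencoder (no corruption)."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.W_enc.shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} != model input width {model.W_enc.shape[0]}"
        )
    z = X @ model.W_enc + model.b_enc
    return z if linear else _sigmoid(z)


@dataclass
class IMCModel:
    """Low-rank bilinear factors of the inductive matrix completion model."""

    W: np.ndarray  # f_d x k
    H: np.ndarray  # f_t x k
    k: int
    alpha: float
    lam: float
    objective_trace: list[float] = field(default_factory=list)


def imc_objective(
    P: np.ndarray, X: np.ndarray, Y: np.ndarray, W: np.ndarray, H: np.ndarray,
    alpha: float, lam: float,
) -> float:
    """The biased PU completion objective for given factors."""
    S = X @ W @ H.T @ Y.T
    pos = P != 0
    sq = (P - S) ** 2
    return float(
        sq[pos].sum()
        + alpha * sq[~pos].sum()
        + lam * ((W**2).sum() + (H**2).sum())
    )


def _solve_W(P, X, B, alpha, lam):
    """Closed-form ridge solve for W with B = Y @ H fixed.

    Weights are alpha everywhere plus (1 - alpha) on positives, so the
    normal matrix splits into a dense Kronecker part and a sparse sum over
    the positive entries.
    """
    f_d, k = X.shape[1], B.shape[1]
    XtX = X.T @ X
    BtB = B.T @ B
    M = alpha * np.kron(BtB, XtX)
    # rhs[p, a] = sum_ij w_ij P_ij x_ip b_ja; P is zero off the observed set
    rhs = alpha * (X.T @ P @ B)
    pos_i, pos_j = np.nonzero(P != 0)
    if pos_i.size:
        Xp = X[pos_i]  # n_obs x f_d
        Bp = B[pos_j]  # n_obs x k
        vals = P[pos_i, pos_j]
        # observed entries carry weight 1 = alpha + (1 - alpha)
        for a in range(k):
            for b in range(k):
                M[a * f_d : (a + 1) * f_d, b * f_d : (b + 1) * f_d] += (1 - alpha) * (
                    Xp * (Bp[:, a] * Bp[:, b])[:, None]
                ).T @ Xp
        rhs += (1 - alpha) * (Xp.T @ (Bp * vals[:, None]))
    M += lam * np.eye(f_d * k)
    w = np.linalg.solve(M, rhs.reshape(-1, order="F"))
    return w.reshape((f_d, k), order="F")


def fit_imc(
    data: DrugTargetData,
    k: int = 5,
    alpha: float = 0.1,
    lam: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> IMCModel:
    """Alternating least squares for the biased PU completion objective.

    Each half-step solves one factor exactly with the other fixed, so the
    recorded ``objective_trace`` is non-increasing.  Iteration stops when
    the relative objective change drops below ``tol``.
    """
    P, X, Y = np.asarray(data.P, float), np.asarray(data.X, float), np.asarray(data.Y, float)
    if k > min(P.shape):
        raise ValueError("k must not exceed min(n_drugs, n_targets)")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lam = max(lam, 1e-12)  # keeps the normal equations nonsingular
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((X.shape[1], k)) / np.sqrt(X.shape[1])
    H = rng.standard_normal((Y.shape[1], k)) / np.sqrt(Y.shape[1])

    trace = [imc_objective(P, X, Y, W, H, alpha, lam)]
    for _ in range(max_iter):
        W = _solve_W(P, X, Y @ H, alpha, lam)
        H = _solve_W(P.T, Y, X @ W, alpha, lam)
        trace.append(imc_objective(P, X, Y, W, H, alpha, lam))
        if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), 1e-12):
            break
    return IMCModel(W=W, H=H, k=k, alpha=alpha, lam=lam, objective_trace=trace)


def predict_scores(model: IMCModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise interaction scores ``Score(i, j) = x_i W H^T y_j^T``."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[1] != model.W.shape[0] or Y.shape[1] != model.H.shape[0]:
        raise ValueError("feature widths do not match the fitted factors")
    return X @ model.W @ model.H.T @ Y.T


def top_predictions(
    scores: np.ndarray, P: np.ndarray, top_k: int = 10
) -> list[tuple[int, int, float]]:
    """The ``top_k`` highest-scoring unobserved pairs.

    Only entries with ``P_ij = 0`` are candidates; ties are broken by
    (row, column) lexicographic order.
    """
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    scores, P = np.asarray(scores, float), np.asarray(P, float)
    cand_i, cand_j = np.nonzero(P == 0)
    if cand_i.size == 0:
        return []
    vals = scores[cand_i, cand_j]
    order = np.lexsort((cand_j, cand_i, -vals))
    return [
        (int(cand_i[o]), int(cand_j[o]), float(vals[o])) for o in order[:top_k]
    ]
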