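"""L2-regularized least-squares deconvolution of the forward model.

The conventional model-based baseline solves

    X_hat = argmin_X  1/2 ||Y - A X||^2 + alpha/2 ||X||^2

with A the propagation matrix and Y the vectorized RF data.  The problem
is exactly ridge regression; it is solved iteratively with FISTA (for an
L2 penalty the proximal step is a simple shrinkage by 1/(1+step*alpha),
folded here into the gradient since the objective is smooth), and a dense
closed form ``(A'A + alpha I)^-1 A'Y`` is provided as an exact oracle for
grids small enough to factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .forward import RFData, SystemMatrix

__all__ = ["DeconvConfig", "fista_l2", "ridge_closed_form", "tune_alpha"]


@dataclass
class DeconvConfig:
    alpha: float = 0.1
    n_iter: int = 200
    tol: float = 1e-6
    step: float | None = None  # None -> 1/L via power iteration
    n_power_iter: int = 50

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


def _lipschitz(A: np.ndarray, alpha: float, n_iter: int, seed: int = 0) -> float:
    """Largest eigenvalue of A'A + alpha I by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        w = A.T @ (A @ v) + alpha * v
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return alpha if alpha > 0 else 1.0
        v = w / lam
    return lam


def fista_l2(Y, A, cfg: DeconvConfig):
    """Accelerated gradient minimization of the ridge objective.

    ``Y`` may be an RFData or a vector; ``A`` a SystemMatrix or 2D array.
    Returns ``(x_hat, trace)`` where ``x_hat`` is the flattened solution
    (reshape with the grid when A is a SystemMatrix) and ``trace`` the
    per-iteration objective values.
    """
    grid_shape = None
    if isinstance(A, SystemMatrix):
        grid_shape = A.grid_shape
        A = A.entries
    if isinstance(Y, RFData):
        Y = Y.signals
    y = np.asarray(Y, dtype=float).ravel()
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty system matrix")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(A))):
        raise ValueError("non-finite inputs")
    if A.shape[0] != y.size:
        raise ValueError(f"A has {A.shape[0]} rows but Y has {y.size} samples")

    if cfg.step is not None:
        step = cfg.step
    else:
        step = 1.0 / _lipschitz(A, cfg.alpha, cfg.n_power_iter)

    def objective(x):
        r = y - A @ x
        return 0.5 * float(r @ r) + 0.5 * cfg.alpha * float(x @ x)

    x = np.zeros(A.shape[1])
    z = x.copy()
    t = 1.0
    trace = [objective(x)]
    for _ in range(cfg.n_iter):
        grad = A.T @ (A @ z - y) + cfg.alpha * z
        x_new = z - step * grad
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + (t - 1.0) / t_new * (x_new - x)
        dx = np.linalg.norm(x_new - x) / max(np.linalg.norm(x_new), 1e-30)
        x, t = x_new, t_new
        trace.append(objective(x))
        if dx < cfg.tol:
            break
    if grid_shape is not None:
        return x.reshape(grid_shape), np.asarray(trace)
    return x, np.asarray(trace)


def ridge_closed_form(Y, A, alpha: float) -> np.ndarray:
    """Exact ridge minimizer (A'A + alpha I)^-1 A'Y (oracle-scale only)."""
    grid_shape = None
    if isinstance(A, SystemMatrix):
        grid_shape = A.grid_shape
        A = A.entries
    if isinstance(Y, RFData):
        Y = Y.signals
    y = np.asarray(Y, dtype=float).ravel()
    A = np.asarray(A, dtype=float)
    G = A.T @ A + alpha * np.eye(A.shape[1])
    x = linalg.solve(G, A.T @ y, assume_a="pos")
    return x.reshape(grid_shape) if grid_shape is not None else x


def tune_alpha(Y, A, truth: np.ndarray, alphas, cfg: DeconvConfig | None = None):
    """Pick alpha maximizing sSSIM of the reconstruction against a known
    ground truth — the automated analogue of tuning the regularization by
    visually comparing with the reference image."""
    from .metrics import sssim

    cfg = cfg or DeconvConfig()
    best = (None, -np.inf, None)
    for a in alphas:
        c = DeconvConfig(alpha=float(a), n_iter=cfg.n_iter, tol=cfg.tol)
        x, _ = fista_l2(Y, A, c)
        img = x.reshape(truth.shape)
        score = sssim(img, truth)
        if score > best[1]:
            best = (float(a), score, img)
    return best
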