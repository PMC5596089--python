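"""Bayesian linear discriminant analysis with evidence-framework precisions.

Regression of +/-1 epoch labels onto feature vectors under a Gaussian
likelihood (noise precision ``beta``) and a zero-mean Gaussian prior with
precision ``alpha`` on the feature weights and a separate, near-flat
precision ``epsilon`` on the bias weight.  The posterior is Gaussian,

    m = beta * (beta * X X^T + I'(alpha))^-1 X t
    C =        (beta * X X^T + I'(alpha))^-1

with I'(alpha) = diag(alpha, ..., alpha, epsilon); predictions for a new
augmented vector x_hat are mu = m^T x_hat, sigma^2 = 1/beta + x_hat^T C x_hat.
``alpha`` and ``beta`` are estimated by fixed-point evidence maximisation
(MacKay-style updates) unless held fixed.

Convention: feature matrices are P' x Q with observations as *columns* and
the bias slot as the *last* row (a constant 1 appended to every feature
vector).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigvalsh

__all__ = [
    "BldaModel",
    "augment_bias",
    "build_training_set",
    "fit",
    "predict_mean",
    "predict_variance",
    "save_model",
    "load_model",
]


@dataclass
class BldaModel:
    m: np.ndarray                 # posterior mean, length P' (bias last)
    C: np.ndarray                 # posterior covariance, P' x P'
    alpha: float                  # prior precision on feature weights
    beta: float                   # noise precision
    epsilon: float                # prior precision on the bias weight
    n_iter: int = 0
    converged: bool = True
    meta: dict | None = None      # preprocessing provenance (band, step, ...)

    @property
    def n_weights(self) -> int:
        return self.m.size

    def predict_mean(self, x_hat: np.ndarray) -> float:
        return predict_mean(self, x_hat)

    def predict_variance(self, x_hat: np.ndarray) -> float:
        return predict_variance(self, x_hat)


def augment_bias(x: np.ndarray) -> np.ndarray:
    """Append the constant-1 bias coordinate.

    Accepts a single vector (returns length P+1) or a P x Q column matrix
    (returns (P+1) x Q).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.concatenate([x, [1.0]])
    if x.ndim == 2:
        return np.vstack([x, np.ones((1, x.shape[1]))])
    raise ValueError("expected a vector or a P x Q matrix")


def build_training_set(features) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled feature vectors into (X, t) with X bias-augmented.

    ``features`` is an iterable of :class:`~mindreach.preprocess.FeatureVector`
    with ``is_target`` set; targets map to +1, non-targets to -1.
    """
    cols, labels = [], []
    for f in features:
        if f.is_target is None:
            raise ValueError(
                f"feature (trial {f.trial_index}, round {f.round_index}, "
                f"key {f.key_id}) has no target label"
            )
        cols.append(f.x)
        labels.append(1.0 if f.is_target else -1.0)
    if not cols:
        raise ValueError("empty training set")
    X = augment_bias(np.asarray(cols, dtype=float).T)
    t = np.asarray(labels, dtype=float)
    return X, t


def _iprime(p1: int, alpha: float, epsilon: float) -> np.ndarray:
    d = np.full(p1, alpha)
    d[-1] = epsilon
    return d


def fit(
    X: np.ndarray,
    t: np.ndarray,
    epsilon: float = 1e-10,
    tol: float = 1e-6,
    max_iter: int = 500,
    alpha0: float = 1.0,
    beta0: float = 1.0,
    optimize: bool = True,
    meta: dict | None = None,
) -> BldaModel:
    """Fit the discriminant; ``optimize=False`` keeps (alpha0, beta0) fixed.

    The evidence updates are

        gamma = sum_i  beta*lam_i / (beta*lam_i + alpha)
        alpha <- gamma / (m^T m over the feature slots)
        beta  <- (Q - gamma) / ||X^T m - t||^2

    with lam_i the eigenvalues of X X^T restricted to the feature (non-bias)
    block; iteration stops when the relative change of (alpha, beta) drops
    below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a P' x Q matrix (observations as columns)")
    p1, q = X.shape
    if t.size != q:
        raise ValueError(f"t has {t.size} entries but X has {q} columns")
    if q < 2:
        raise ValueError("need at least two training observations")
    if np.all(t > 0) or np.all(t < 0):
        raise ValueError("training labels contain a single class")

    G = X @ X.T
    Xt = X @ t
    alpha, beta = float(alpha0), float(beta0)

    def solve(a: float, b: float) -> tuple[np.ndarray, object]:
        A = b * G + np.diag(_iprime(p1, a, epsilon))
        try:
            cho = cho_factor(A, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "posterior precision matrix is singular; increase epsilon or "
                "the alpha floor (more regularisation)"
            ) from exc
        return b * cho_solve(cho, Xt), cho

    n_iter = 0
    converged = not optimize
    if optimize:
        lam = eigvalsh(G[:-1, :-1])
        lam = np.clip(lam, 0.0, None)
        for n_iter in range(1, max_iter + 1):
            m, _ = solve(alpha, beta)
            gamma = float(np.sum(beta * lam / (beta * lam + alpha)))
            mm = float(m[:-1] @ m[:-1])
            resid = float(np.sum((X.T @ m - t) ** 2))
            alpha_new = gamma / max(mm, 1e-300)
            beta_new = max(q - gamma, 1e-12) / max(resid, 1e-300)
            rel = max(
                abs(alpha_new - alpha) / max(abs(alpha), 1e-300),
                abs(beta_new - beta) / max(abs(beta), 1e-300),
            )
            alpha, beta = alpha_new, beta_new
            if rel < tol:
                converged = True
                break

    m, cho = solve(alpha, beta)
    C = cho_solve(cho, np.eye(p1))
    C = 0.5 * (C + C.T)
    return BldaModel(
        m=m, C=C, alpha=alpha, beta=beta, epsilon=epsilon,
        n_iter=n_iter, converged=converged, meta=meta,
    )


def predict_mean(model: BldaModel, x_hat: np.ndarray) -> float:
    """Predictive mean mu = m^T x_hat (x_hat already bias-augmented)."""
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x_hat.size != model.m.size:
        raise ValueError(
            f"x_hat has {x_hat.size} entries, model expects {model.m.size} "
            "(did you forget the bias coordinate?)"
        )
    return float(model.m @ x_hat)


def predict_variance(model: BldaModel, x_hat: np.ndarray) -> float:
    """Predictive variance sigma^2 = 1/beta + x_hat^T C x_hat."""
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x_hat.size != model.m.size:
        raise ValueError(
            f"x_hat has {x_hat.size} entries, model expects {model.m.size}"
        )
    return float(1.0 / model.beta + x_hat @ model.C @ x_hat)


# ---------------------------------------------------------------------------
# Serialization: one self-describing JSON-headed text archive
# ---------------------------------------------------------------------------

def save_model(model: BldaModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "format": "mindreach-blda",
        "version": 1,
        "alpha": model.alpha,
        "beta": model.beta,
        "epsilon": model.epsilon,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "n_weights": int(model.m.size),
        "meta": model.meta or {},
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, model.m[None, :], fmt="%.17g", delimiter="\t")
        np.savetxt(fh, model.C, fmt="%.17g", delimiter="\t")
    return path


def load_model(path: str | Path) -> BldaModel:
    path = Path(path)
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "mindreach-blda":
            raise ValueError(f"{path}: not a blda model archive")
        m = np.loadtxt([fh.readline()], delimiter="\t")
        C = np.loadtxt(fh, delimiter="\t", ndmin=2)
    n = header["n_weights"]
    if m.size != n or C.shape != (n, n):
        raise ValueError(f"{path}: inconsistent archive dimensions")
    return BldaModel(
        m=m, C=C, alpha=header["alpha"], beta=header["beta"],
        epsilon=header["epsilon"], n_iter=header["n_iter"],
        converged=header["converged"], meta=header.get("meta") or None,
    )
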