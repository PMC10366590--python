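"""Broad Learning System (BLS) core.

A BLS is a flat learner: random *feature nodes* D = phi(X W_e + beta_e) and
random *enhancement nodes* E = delta(S W_h + beta_h) are concatenated into
a state matrix G = [D | E], and the only trained parameters are the output
weights W solving the ridge objective

    min_W  ||Y - G W||^2 + lam ||W||^2,

in closed form via the ridge pseudo-inverse G+ = (lam I + G'G)^(-1) G'
(the Moore-Penrose pseudo-inverse in the limit lam -> 0).  No
backpropagation, no iterations, no local optima.

Two wirings are supported, selected explicitly by ``mode``:

* ``classic``  - the original BLS: enhancement nodes read the feature-node
  block D (source S = D); the raw input is X.
* ``ensemble`` - the deep-broad ensemble: feature nodes read the shallow
  convolutional vector x_d and enhancement nodes read the *deep* vector
  x_e directly (S = X_e), not D.

Mapping weights can optionally be refined by sparse auto-coding: an
ISTA-solved lasso that re-expresses the input in the random feature basis,
yielding sparser, more structured mapping weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg
from scipy.special import expit, softmax

from ._exceptions import ConfigurationError, NotFittedError, StructuralError

log = logging.getLogger(__name__)

__all__ = [
    "BLSConfig",
    "BLSParams",
    "StateMatrix",
    "LabelMatrix",
    "ACTIVATIONS",
    "feature_nodes",
    "enhancement_nodes",
    "sparse_autoencode_weights",
    "ridge_pinv",
    "fit_output_weights",
    "ridge_objective",
    "fit",
    "predict",
    "predict_proba",
]

ACTIVATIONS = {
    "identity": lambda z: z,
    "tanh": np.tanh,
    "sigmoid": expit,
    "relu": lambda z: np.maximum(z, 0.0),
}

# Hyperparameter ranges of the published sweep; enforced only in sweep mode.
SWEEP_FEATURE_RANGE = (500, 4000)
SWEEP_ENH_RANGE = (100, 1000)
SWEEP_SPARSITY_RANGE = (0.4, 0.7)


@dataclass
class BLSConfig:
    """Hyperparameters of the broad learner.

    phi defaults to identity (the mapping layer may be linear) and delta to
    tanh (the enhancement layer must be non-linear).  ``lam`` defaults to a
    tiny ridge, 1e-8: the closed form takes lam -> 0 but an exact zero is
    numerically unsafe.  Nodes are organised in equal-width groups
    (``total = groups * width``); group counts must divide node totals.

    ``enh_weight_scale`` scales the uniform[-1,1] enhancement weights by
    1/sqrt(source_dim) times its value, keeping tanh pre-activations O(1)
    for standardized high-dimensional sources.  ``sweep_mode`` validates
    node counts / sparsity against the published sweep ranges.
    """

    n_feature_nodes: int = 1000
    n_feature_groups: int = 10
    n_enh_nodes: int = 500
    n_enh_groups: int = 5
    phi: str = "identity"
    delta: str = "tanh"
    lam: float = 1e-8
    sparsity: float = 0.5
    use_sparse_autoencoder: bool = False
    sae_max_iter: int = 50
    sae_tol: float = 1e-6
    seed: int = 0
    mode: str = "ensemble"
    hybrid_enhancement: bool = False
    standardize: bool = True
    enh_weight_scale: float = 1.0
    sweep_mode: bool = False

    def __post_init__(self):
        for name in (self.phi, self.delta):
            if name not in ACTIVATIONS:
                raise ConfigurationError(
                    f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
                )
        if self.mode not in ("classic", "ensemble"):
            raise ConfigurationError("mode must be 'classic' or 'ensemble'")
        if self.lam <= 0:
            raise ConfigurationError("lam must be > 0")
        if self.n_feature_nodes % self.n_feature_groups:
            raise ConfigurationError("n_feature_groups must divide n_feature_nodes")
        if self.n_enh_nodes % self.n_enh_groups:
            raise ConfigurationError("n_enh_groups must divide n_enh_nodes")
        if self.sweep_mode:
            lo, hi = SWEEP_FEATURE_RANGE
            if not lo <= self.n_feature_nodes <= hi:
                raise ConfigurationError(
                    f"sweep mode: n_feature_nodes must be in [{lo}, {hi}]"
                )
            lo, hi = SWEEP_ENH_RANGE
            if not lo <= self.n_enh_nodes <= hi:
                raise ConfigurationError(f"sweep mode: n_enh_nodes must be in [{lo}, {hi}]")
            lo, hi = SWEEP_SPARSITY_RANGE
            if self.use_sparse_autoencoder and not lo <= self.sparsity <= hi:
                raise ConfigurationError(f"sweep mode: sparsity must be in [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, d: dict) -> "BLSConfig":
        return cls(**d)


@dataclass
class LabelMatrix:
    """One-hot label matrix with its ordered class names."""

    Y: np.ndarray
    class_names: list

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.class_names):
            raise StructuralError("Y must be (n_samples, n_classes)")
        if not (np.isin(self.Y, (0.0, 1.0)).all() and (self.Y.sum(axis=1) == 1).all()):
            raise StructuralError("Y rows must be one-hot")

    @classmethod
    def from_labels(cls, labels, class_names=None) -> "LabelMatrix":
        labels = np.asarray(labels)
        if class_names is None:
            class_names = sorted(np.unique(labels).tolist())
        idx = {c: i for i, c in enumerate(class_names)}
        Y = np.zeros((len(labels), len(class_names)))
        for r, lab in enumerate(labels):
            Y[r, idx[lab]] = 1.0
        return cls(Y=Y, class_names=list(class_names))


@dataclass
class StateMatrix:
    """Feature block D, enhancement block E and their concatenation G."""

    D: np.ndarray
    E: np.ndarray

    def __post_init__(self):
        if self.D.shape[0] != self.E.shape[0]:
            raise StructuralError("D and E must have equal row counts")

    @property
    def G(self) -> np.ndarray:
        return np.hstack([self.D, self.E])


@dataclass
class BLSParams:
    """All random weights/biases plus the learned output weights.

    ``W_out`` is ``None`` until :func:`fit` has run.  Standardization
    statistics of the training inputs are stored so prediction applies the
    identical transform.
    """

    config: BLSConfig
    W_e: np.ndarray = None
    beta_e: np.ndarray = None
    W_h: np.ndarray = None
    beta_h: np.ndarray = None
    W_out: Optional[np.ndarray] = None
    class_names: list = field(default_factory=list)
    mu_d: np.ndarray = None
    sd_d: np.ndarray = None
    mu_e: np.ndarray = None
    sd_e: np.ndarray = None

    @property
    def fitted(self) -> bool:
        return self.W_out is not None


# ---------------------------------------------------------------------------
# node computations
# ---------------------------------------------------------------------------


def feature_nodes(X, p: BLSParams) -> np.ndarray:
    """Feature-node block D = phi(X W_e + beta_e).

    Columns are the concatenation of the equal-width node groups d_i.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != p.W_e.shape[0]:
        raise StructuralError(
            f"input dim {X.shape[1]} != mapping weight rows {p.W_e.shape[0]}"
        )
    phi = ACTIVATIONS[p.config.phi]
    return phi(X @ p.W_e + p.beta_e)


def enhancement_nodes(source, p: BLSParams) -> np.ndarray:
    """Enhancement block E = delta(S W_h + beta_h).

    The source S is the feature block D in classic mode and the deep vector
    matrix X_e in ensemble mode; the caller selects it explicitly.
    """
    S = np.asarray(source, dtype=float)
    if S.shape[1] != p.W_h.shape[0]:
        raise StructuralError(
            f"source dim {S.shape[1]} != enhancement weight rows {p.W_h.shape[0]}"
        )
    delta = ACTIVATIONS[p.config.delta]
    return delta(S @ p.W_h + p.beta_h)


def sparse_autoencode_weights(X, W_init, sparsity, beta_init=None, phi="identity",
                              max_iter=50, tol=1e-6):
    """Refine random mapping weights by sparse auto-coding (lasso/ISTA).

    With random features Z = phi(X W_init + beta_init), solves

        min_W ||Z W - X||_F^2 + sparsity * ||W||_1

    by iterative soft-thresholding and returns W.T, shaped like a mapping
    weight matrix (input_dim x n_nodes).  ``sparsity = 0`` reduces to the
    plain least-squares solution.  Deterministic given its inputs.
    """
    X = np.asarray(X, dtype=float)
    W_init = np.asarray(W_init, dtype=float)
    if sparsity < 0:
        raise ValueError("sparsity must be >= 0")
    act = ACTIVATIONS[phi] if isinstance(phi, str) else phi
    Z = act(X @ W_init + (0.0 if beta_init is None else beta_init))

    if sparsity == 0:
        W, *_ = np.linalg.lstsq(Z, X, rcond=None)
        return W.T

    # ISTA on f(W) = ||ZW - X||^2 + s||W||_1; gradient Lipschitz 2*||Z||_2^2
    L = np.linalg.norm(Z, 2) ** 2
    if L == 0:
        return np.zeros((X.shape[1], Z.shape[1]))
    step = 1.0 / (2.0 * L)
    thresh = sparsity * step
    W = np.zeros((Z.shape[1], X.shape[1]))
    ZtZ, ZtX = Z.T @ Z, Z.T @ X
    converged = False
    for _ in range(max_iter):
        grad = 2.0 * (ZtZ @ W - ZtX)
        W_new = W - step * grad
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - thresh, 0.0)
        delta = np.max(np.abs(W_new - W)) if W_new.size else 0.0
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"sparse auto-coding did not converge within {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    return W.T


# ---------------------------------------------------------------------------
# closed-form solve
# ---------------------------------------------------------------------------


def ridge_pinv(G, lam) -> np.ndarray:
    """Ridge pseudo-inverse G+ = (lam I + G'G)^(-1) G'.

    Computed by a symmetric positive-definite solve; no explicit matrix
    inverse is formed.
    """
    G = np.asarray(G, dtype=float)
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not np.all(np.isfinite(G)):
        raise ValueError("G contains non-finite entries")
    A = G.T @ G
    A[np.diag_indices_from(A)] += lam
    return linalg.solve(A, G.T, assume_a="pos")


def fit_output_weights(G, Y, lam) -> np.ndarray:
    """Closed-form output weights W = G+ Y, the ridge-objective minimizer."""
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape[0] != Y.shape[0]:
        raise StructuralError("G and Y must have equal row counts")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not np.all(np.isfinite(G)):
        raise ValueError("G contains non-finite entries")
    A = G.T @ G
    A[np.diag_indices_from(A)] += lam
    return linalg.solve(A, G.T @ Y, assume_a="pos")


def ridge_objective(G, Y, W, lam) -> float:
    """The training objective ||Y - G W||^2 + lam ||W||^2."""
    R = np.asarray(Y) - np.asarray(G) @ np.asarray(W)
    return float(np.sum(R * R) + lam * np.sum(np.asarray(W) ** 2))


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------


def _standardize_stats(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _uniform_groups(rng, rows, width, groups, scale=1.0):
    """Draw a (rows x groups*width) matrix group by group, uniform [-1, 1]."""
    return np.hstack([rng.uniform(-1.0, 1.0, size=(rows, width)) for _ in range(groups)]) * scale


def _enhancement_source(p: BLSParams, D, X_e_std):
    if p.config.mode == "classic":
        return np.hstack([D, X_e_std]) if p.config.hybrid_enhancement else D
    return np.hstack([D, X_e_std]) if p.config.hybrid_enhancement else X_e_std


def fit(X_d, X_e, Y, config: BLSConfig | None = None) -> BLSParams:
    """Train a BLS in closed form.

    Parameters
    ----------
    X_d : (n, d) array
        Input of the feature-mapping layer (shallow conv vectors in
        ensemble mode; the raw features in classic mode).
    X_e : (n, e) array or None
        Input of the enhancement layer in ensemble mode.  Ignored in
        classic mode (may be None).
    Y : LabelMatrix or 1D label array
    """
    config = config or BLSConfig()
    X_d = np.asarray(X_d, dtype=float)
    if not isinstance(Y, LabelMatrix):
        Y = LabelMatrix.from_labels(Y)
    if X_d.shape[0] != Y.Y.shape[0]:
        raise StructuralError("X_d and Y must have equal row counts")
    if config.mode == "ensemble":
        if X_e is None:
            raise StructuralError("ensemble mode requires X_e")
        X_e = np.asarray(X_e, dtype=float)
        if X_e.shape[0] != X_d.shape[0]:
            raise StructuralError("X_d and X_e must have equal row counts")

    p = BLSParams(config=config, class_names=list(Y.class_names))

    if config.standardize:
        p.mu_d, p.sd_d = _standardize_stats(X_d)
        Xd_std = (X_d - p.mu_d) / p.sd_d
        if config.mode == "ensemble" or config.hybrid_enhancement:
            p.mu_e, p.sd_e = _standardize_stats(X_e)
            Xe_std = (X_e - p.mu_e) / p.sd_e
        else:
            Xe_std = None
    else:
        Xd_std = X_d
        Xe_std = np.asarray(X_e, dtype=float) if X_e is not None else None

    rng = np.random.default_rng(config.seed)
    d_in = Xd_std.shape[1]
    p.W_e = _uniform_groups(rng, d_in, config.n_feature_nodes // config.n_feature_groups,
                            config.n_feature_groups)
    p.beta_e = rng.uniform(-1.0, 1.0, size=config.n_feature_nodes)

    if config.use_sparse_autoencoder:
        p.W_e = sparse_autoencode_weights(
            Xd_std, p.W_e, config.sparsity, beta_init=p.beta_e, phi=config.phi,
            max_iter=config.sae_max_iter, tol=config.sae_tol,
        )

    D = feature_nodes(Xd_std, p)

    if config.mode == "classic" and not config.hybrid_enhancement:
        src_dim = D.shape[1]
    elif config.hybrid_enhancement:
        src_dim = D.shape[1] + Xe_std.shape[1]
    else:
        src_dim = Xe_std.shape[1]
    scale = config.enh_weight_scale / np.sqrt(src_dim)
    p.W_h = _uniform_groups(rng, src_dim, config.n_enh_nodes // config.n_enh_groups,
                            config.n_enh_groups, scale=scale)
    p.beta_h = rng.uniform(-1.0, 1.0, size=config.n_enh_nodes) * scale

    E = enhancement_nodes(_enhancement_source(p, D, Xe_std), p)
    G = StateMatrix(D=D, E=E).G
    p.W_out = fit_output_weights(G, Y.Y, config.lam)
    return p


def _state_matrix(p: BLSParams, X_d, X_e) -> np.ndarray:
    X_d = np.asarray(X_d, dtype=float)
    needs_e = p.config.mode == "ensemble" or p.config.hybrid_enhancement
    if needs_e and X_e is None:
        raise StructuralError("this model requires X_e")
    if p.config.standardize:
        Xd_std = (X_d - p.mu_d) / p.sd_d
        Xe_std = (np.asarray(X_e, dtype=float) - p.mu_e) / p.sd_e if needs_e else None
    else:
        Xd_std = X_d
        Xe_std = np.asarray(X_e, dtype=float) if X_e is not None else None
    D = feature_nodes(Xd_std, p)
    E = enhancement_nodes(_enhancement_source(p, D, Xe_std), p)
    return StateMatrix(D=D, E=E).G


def predict(p: BLSParams, X_d, X_e=None):
    """Linear scores G W_out and argmax labels (first-index tie-break)."""
    if not p.fitted:
        raise NotFittedError("model has no output weights; call fit() first")
    G = _state_matrix(p, X_d, X_e)
    scores = G @ p.W_out
    idx = np.argmax(scores, axis=1)  # np.argmax breaks ties at the first index
    labels = np.asarray(p.class_names, dtype=object)[idx]
    return scores, labels


def predict_proba(p: BLSParams, X_d, X_e=None) -> np.ndarray:
    """Softmax of the linear scores.

    A monotone, calibration-free transform exposed as the "probability"
    view; ranking-based metrics (ROC) should use the raw scores.
    """
    scores, _ = predict(p, X_d, X_e)
    return softmax(scores, axis=1)
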