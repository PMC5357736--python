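"""Two-class PLS-DA by NIPALS, with repeated-measures-aware scaling.

The classifier regresses a +/-1 class code (diet 1 -> +1, diet 4 -> -1) on
the high-dimensional spectrum matrix.  Latent variables are extracted by the
deterministic NIPALS sequence (weight w proportional to X'y), and the
regression coefficient vector is assembled as ``beta = W (P'W)^-1 c`` so
that predictions for new samples are a single matrix-vector product on the
centred/scaled spectra.

Repeated measures: with ``subject_centring`` the training matrix is reduced
by each subject's mean row (multilevel/within-subject decomposition) before
column scales are computed, removing between-person concentration offsets
from the model.  External samples from single-visit cohorts have no subject
mean, so prediction applies grand-mean column centring and the within-
subject scales only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalingModel", "PLSModel", "fit_scaling", "fit_pls",
           "fit_plsda", "predict_scores"]


@dataclass
class ScalingModel:
    """Column centring/scaling learned on a training matrix.

    ``column_means`` are the raw grand column means (used to centre unseen
    samples); ``column_scales`` are computed on the within-subject matrix
    when ``subject_centring`` is set.  Zero-variance columns keep scale 1
    and are flagged in ``constant_columns``.
    """

    column_means: np.ndarray
    column_scales: np.ndarray
    mode: str = "autoscale"
    subject_centring: bool = False
    subject_means: dict | None = None
    constant_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.column_scales <= 0):
            raise ValueError("column scales must be strictly positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Centre by the grand mean and scale: for unseen/external samples."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.column_means.shape[0]:
            raise ValueError("variable count mismatch with scaling model")
        return (X - self.column_means) / self.column_scales

    def transform_train(self, X: np.ndarray, subjects=None) -> np.ndarray:
        """Training-side transform; removes subject mean rows when enabled."""
        X = np.asarray(X, dtype=float)
        if not self.subject_centring:
            return self.transform(X)
        if subjects is None:
            raise ValueError("subject ids required for subject centring")
        centred = np.empty_like(X, dtype=float)
        for i, s in enumerate(subjects):
            centred[i] = X[i] - self.subject_means[s]
        return centred / self.column_scales


def fit_scaling(
    X: np.ndarray,
    subjects=None,
    mode: str = "autoscale",
    subject_centring: bool = False,
) -> ScalingModel:
    """Learn centring/scaling from a training matrix.

    ``mode``: 'autoscale' (unit variance, sample SD with n-1 denominator),
    'pareto' (sqrt of the SD) or 'none' (centring only, scales all 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if mode not in ("autoscale", "pareto", "none"):
        raise ValueError(f"unknown scaling mode: {mode}")
    grand = X.mean(axis=0)
    subject_means = None
    if subject_centring:
        if subjects is None or len(subjects) != X.shape[0]:
            raise ValueError("one subject id per row required")
        subject_means = {}
        subjects = list(subjects)
        for s in set(subjects):
            rows = [i for i, t in enumerate(subjects) if t == s]
            subject_means[s] = X[rows].mean(axis=0)
        within = X - np.array([subject_means[s] for s in subjects])
    else:
        within = X - grand
    sd = within.std(axis=0, ddof=1)
    constant = sd <= np.finfo(float).eps * max(1.0, np.abs(X).max())
    if constant.all() and mode == "autoscale":
        warnings.warn("all columns have zero variance; scales set to 1")
    if mode == "autoscale":
        scales = np.where(constant, 1.0, np.where(sd > 0, sd, 1.0))
    elif mode == "pareto":
        scales = np.where(constant, 1.0, np.sqrt(np.where(sd > 0, sd, 1.0)))
    else:
        scales = np.ones_like(sd)
    return ScalingModel(
        column_means=grand,
        column_scales=scales,
        mode=mode,
        subject_centring=subject_centring,
        subject_means=subject_means,
        constant_columns=constant,
    )


@dataclass
class PLSModel:
    """A fitted two-class PLS-DA model."""

    n_components: int
    weights: np.ndarray       # W: n_vars x A
    loadings: np.ndarray      # P: n_vars x A
    y_loadings: np.ndarray    # c: A
    scores: np.ndarray        # T: n_train x A
    beta: np.ndarray          # n_vars
    class_encoding: dict = field(default_factory=lambda: {1: +1, 4: -1})
    scaling: ScalingModel | None = None


def fit_pls(X_scaled: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """NIPALS PLS1 on an already centred/scaled matrix.

    Per component: w ∝ X'y (unit length), t = Xw, c = t'y/t't, p = X't/t't,
    then X is deflated by t p'.  Components whose score variance collapses
    to numerical zero are truncated with a warning.
    """
    X = np.array(X_scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("y must be one value per row of X")
    if len(np.unique(np.sign(y[y != 0]))) < 2 and len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    max_a = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_a:
        raise ValueError(f"n_components {n_components} exceeds limit {max_a}")

    n_vars = X.shape[1]
    W = np.zeros((n_vars, n_components))
    P = np.zeros((n_vars, n_components))
    c = np.zeros(n_components)
    T = np.zeros((X.shape[0], n_components))
    tol = np.finfo(float).eps * 100
    x_norm0 = np.linalg.norm(X) or 1.0
    kept = 0
    for a in range(n_components):
        w = X.T @ y
        w_norm = np.linalg.norm(w)
        if w_norm <= tol * x_norm0:
            warnings.warn(
                f"component {a + 1}: residual X carries no covariance with y;"
                f" truncating to {kept} components"
            )
            break
        w = w / w_norm
        t = X @ w
        tt = float(t @ t)
        if tt <= (tol * x_norm0) ** 2:
            warnings.warn(
                f"component {a + 1}: degenerate score variance; truncating"
            )
            break
        W[:, a] = w
        T[:, a] = t
        c[a] = float(t @ y) / tt
        P[:, a] = X.T @ t / tt
        X = X - np.outer(t, P[:, a])
        kept += 1
    W, P, c, T = W[:, :kept], P[:, :kept], c[:kept], T[:, :kept]
    if kept == 0:
        raise ValueError("no usable PLS component (X has no covariance with y)")
    beta = W @ np.linalg.solve(P.T @ W, c)
    return PLSModel(
        n_components=kept, weights=W, loadings=P, y_loadings=c,
        scores=T, beta=beta,
    )


def fit_plsda(
    X: np.ndarray,
    diets,
    subjects=None,
    positive_class=1,
    negative_class=4,
    n_components: int = 2,
    mode: str = "autoscale",
    subject_centring: bool = True,
) -> PLSModel:
    """Scaling + NIPALS fit from raw intensities and diet labels."""
    diets = list(diets)
    y = np.array(
        [+1.0 if d == positive_class else -1.0 for d in diets]
    )
    if not (any(d == positive_class for d in diets)
            and any(d == negative_class for d in diets)):
        raise ValueError("both classes must be present")
    scaling = fit_scaling(X, subjects=subjects, mode=mode,
                          subject_centring=subject_centring)
    Xs = scaling.transform_train(X, subjects=subjects)
    model = fit_pls(Xs, y, n_components)
    model.class_encoding = {positive_class: +1, negative_class: -1}
    model.scaling = scaling
    return model


def predict_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted score for new raw samples: positive resembles the +1 class.

    Applies the model's grand-mean centring and column scaling (never
    subject centring — unseen subjects have no stored mean), then projects
    onto the regression vector.
    """
    if model.scaling is None:
        raise ValueError("model carries no scaling; pass scaled data to beta")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    return model.scaling.transform(X_new) @ model.beta
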