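"""Monte Carlo cross-validated PLS-DA ensemble.

Repeatedly (default 1000 times) hold out a random third of the *subjects*,
fit scaling + PLS-DA on the remaining subjects' samples, and predict the
held-out samples.  A sample's T_pred is the mean of its predictions over
all models in which it sat in the validation set; the variance of those
predictions accompanies it.  The per-group score distribution is summarised
by a kernel density estimate that sums one Gaussian per sample, centred at
its T_pred with its own prediction variance.

The fitted ensemble (per-model regression vectors, scalings and splits) is
retained so that unlabelled or external cohorts can be projected through
every model, and so that the bootstrap significance layer can refit within
each model's training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .pls import fit_plsda
from .spectra import SpectrumMatrix
from .synthetic import substream

__all__ = [
    "MCCVConfig",
    "ModelRecord",
    "MCCVEnsemble",
    "PredictionSummary",
    "DensityEstimate",
    "run_mccv",
    "project",
    "group_kde",
    "mixture_density",
]

#: Variance floor for samples predicted only once (degenerate variance 0).
T_PRED_VAR_FLOOR = 1e-12


@dataclass
class MCCVConfig:
    """Monte Carlo cross-validation settings."""

    n_models: int = 1000
    validation_fraction: float = 1 / 3
    n_components: int = 2
    seed: int = 0
    split_unit: str = "subject"
    scaling_mode: str = "autoscale"
    subject_centring: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.split_unit not in ("subject", "sample"):
            raise ValueError("split_unit must be 'subject' or 'sample'")


@dataclass
class ModelRecord:
    """One MCCV split's fitted model, reduced to what prediction and the
    bootstrap layer need."""

    beta: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    train_units: list
    validation_units: list


@dataclass
class MCCVEnsemble:
    config: MCCVConfig
    models: list[ModelRecord]
    class_encoding: dict
    ppm: np.ndarray
    sample_ids: list[str]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def beta_matrix(self) -> np.ndarray:
        return np.array([m.beta for m in self.models])


@dataclass
class PredictionSummary:
    """Cross-validated predicted-score summary for one sample (T_pred)."""

    sample_id: str
    t_pred_mean: float
    t_pred_var: float
    n_appearances: int

    def __post_init__(self) -> None:
        if self.t_pred_var < 0:
            raise ValueError("variance must be >= 0")
        if self.n_appearances < 1:
            raise ValueError("a summarised sample must appear at least once")


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    group_label: str = ""


def _draw_split(units, fraction, rng, labels_by_unit):
    """Random validation subset leaving both classes in training."""
    n_val = max(1, int(round(fraction * len(units))))
    if n_val >= len(units):
        n_val = len(units) - 1
    for _ in range(100):
        val = sorted(rng.choice(len(units), size=n_val, replace=False))
        val_units = [units[i] for i in val]
        train_units = [u for u in units if u not in val_units]
        train_labels = set()
        for u in train_units:
            train_labels |= labels_by_unit[u]
        if len(train_labels) >= 2:
            return train_units, val_units
    raise RuntimeError("could not draw a training split containing both classes")


def run_mccv(
    matrix: SpectrumMatrix,
    config: MCCVConfig,
    classes=(1, 4),
) -> tuple[MCCVEnsemble, list[PredictionSummary]]:
    """Fit the MCCV-PLS-DA ensemble on the two extreme diet classes.

    ``matrix`` must carry annotations with ``subject_id`` and ``diet``; only
    rows whose diet is in ``classes`` are used.  Splits hold out whole
    subjects by default so that no model shares a subject between training
    and validation.
    """
    positive, negative = classes
    sub = matrix.select_where(diet=list(classes))
    ann = sub.annotation_frame()
    diets = list(ann["diet"])
    subjects = list(ann["subject_id"].astype(str))
    if not (positive in diets and negative in diets):
        raise ValueError(f"both classes {classes} must be present")

    if config.split_unit == "subject":
        units = sorted(set(subjects))
        unit_of_row = subjects
    else:
        units = list(sub.sample_ids)
        unit_of_row = list(sub.sample_ids)
    labels_by_unit: dict = {u: set() for u in units}
    for u, d in zip(unit_of_row, diets):
        labels_by_unit[u].add(d)

    X = sub.intensities
    models: list[ModelRecord] = []
    preds: dict[str, list[float]] = {s: [] for s in sub.sample_ids}
    for m in range(config.n_models):
        rng = substream(config.seed, "mccv-split", m)
        train_units, val_units = _draw_split(
            units, config.validation_fraction, rng, labels_by_unit
        )
        train_rows = [i for i, u in enumerate(unit_of_row) if u in set(train_units)]
        val_rows = [i for i, u in enumerate(unit_of_row) if u in set(val_units)]
        model = fit_plsda(
            X[train_rows],
            [diets[i] for i in train_rows],
            subjects=[subjects[i] for i in train_rows],
            positive_class=positive,
            negative_class=negative,
            n_components=config.n_components,
            mode=config.scaling_mode,
            subject_centring=config.subject_centring,
        )
        scores = model.scaling.transform(X[val_rows]) @ model.beta
        for i, s in zip(val_rows, scores):
            preds[sub.sample_ids[i]].append(float(s))
        models.append(
            ModelRecord(
                beta=model.beta,
                column_means=model.scaling.column_means,
                column_scales=model.scaling.column_scales,
                train_units=list(train_units),
                validation_units=list(val_units),
            )
        )

    summaries = [
        PredictionSummary(
            sample_id=s,
            t_pred_mean=float(np.mean(v)),
            t_pred_var=max(float(np.var(v)), T_PRED_VAR_FLOOR),
            n_appearances=len(v),
        )
        for s, v in preds.items()
        if v
    ]
    ensemble = MCCVEnsemble(
        config=config,
        models=models,
        class_encoding={positive: +1, negative: -1},
        ppm=sub.ppm,
        sample_ids=list(sub.sample_ids),
    )
    return ensemble, summaries


def project(ensemble: MCCVEnsemble, matrix: SpectrumMatrix) -> list[PredictionSummary]:
    """Predict every sample of ``matrix`` with every model of the ensemble.

    Spectra must already be PQN-normalised to the ensemble's training
    reference and share its variable set.
    """
    if matrix.n_points != len(ensemble.ppm) or not np.allclose(
        matrix.ppm, ensemble.ppm
    ):
        raise ValueError("spectral axis mismatch with the ensemble")
    B = np.array([m.beta / m.column_scales for m in ensemble.models])  # M x p
    offsets = np.array(
        [float(m.column_means @ (m.beta / m.column_scales)) for m in ensemble.models]
    )
    scores = matrix.intensities @ B.T - offsets  # n x M
    return [
        PredictionSummary(
            sample_id=s,
            t_pred_mean=float(scores[i].mean()),
            t_pred_var=max(float(scores[i].var()), T_PRED_VAR_FLOOR),
            n_appearances=ensemble.n_models,
        )
        for i, s in enumerate(matrix.sample_ids)
    ]


def mixture_density(summaries: list[PredictionSummary], x, var_floor: float = T_PRED_VAR_FLOOR) -> np.ndarray:
    """Exact Gaussian-mixture density: mean of N(t_pred_mean_i, t_pred_var_i)."""
    if not summaries:
        raise ValueError("empty group")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    dens = np.zeros_like(x)
    for s in summaries:
        sd = np.sqrt(max(s.t_pred_var, var_floor))
        dens += norm.pdf(x, loc=s.t_pred_mean, scale=sd)
    return dens / len(summaries)


def group_kde(
    summaries: list[PredictionSummary],
    group_label: str = "",
    grid: np.ndarray | None = None,
    n_grid: int = 512,
    var_floor: float = 1e-6,
    normalise: bool = True,
) -> DensityEstimate:
    """KDE of a group's predicted scores by summing per-sample Gaussians.

    Each sample contributes a Gaussian with its own prediction variance
    (floored at ``var_floor``); when every variance is at the floor a
    Silverman bandwidth on the means is substituted.  The returned curve is
    renormalised so its trapezoidal integral over the grid is 1.
    """
    if not summaries:
        raise ValueError("empty group")
    means = np.array([s.t_pred_mean for s in summaries])
    variances = np.array([max(s.t_pred_var, 0.0) for s in summaries])
    if np.all(variances <= var_floor) and len(means) > 1 and np.std(means) > 0:
        h = 1.06 * np.std(means, ddof=1) * len(means) ** (-1 / 5)
        variances = np.full_like(variances, h**2)
    else:
        variances = np.maximum(variances, var_floor)
    sds = np.sqrt(variances)
    if grid is None:
        lo = float(np.min(means - 4 * sds))
        hi = float(np.max(means + 4 * sds))
        grid = np.linspace(lo, hi, n_grid)
    dens = np.zeros_like(grid, dtype=float)
    for mu, sd in zip(means, sds):
        dens += norm.pdf(grid, loc=mu, scale=sd)
    dens /= len(means)
    if normalise:
        area = np.trapezoid(dens, grid)
        if area > 0:
            dens = dens / area
    return DensityEstimate(grid=grid, density=dens, group_label=group_label)
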