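"""Bootstrap-based per-variable coefficient significance across the MCCV
ensemble, FDR q-values and metabolite-level calls.

Within each MCCV model's training split, the training *subjects* are
resampled with replacement (preserving the crossover pairing: a resampled
subject brings all of its class rows) and the scaling + PLS fit is repeated;
default 25 resamples per model.  The bootstrap regression coefficients are
pooled over all models and resamples, and each spectral variable gets a
two-sided normal-approximation p-value from the pooled mean and variance:

    p = 2 * (1 - Phi(|beta_mean| / sqrt(beta_var)))

Benjamini-Hochberg converts p-values to FDR q-values, and the signed
Manhattan statistic -log10(q) * sign(beta_mean) is tabulated per ppm.
Variables are aggregated to metabolite calls: a metabolite is called
diet-associated when at least half of its peak-apex variables pass the q
cutoff with a common sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mccv import MCCVEnsemble
from .pls import fit_plsda
from .spectra import SpectrumMatrix
from .synthetic import MetaboliteSignature, substream

__all__ = [
    "MetaboliteCall",
    "bootstrap_coefficients",
    "fdr_qvalues",
    "attach_qvalues",
    "variable_map",
    "call_metabolites",
]

_P_FLOOR = 1e-300  # keeps -log10(q) finite when z underflows the normal tail


@dataclass
class MetaboliteCall:
    metabolite: str
    direction: str | None      # 'diet1-elevated' / 'diet4-elevated' / None
    n_significant_variables: int
    n_variables: int
    called: bool


def bootstrap_coefficients(
    ensemble: MCCVEnsemble,
    matrix: SpectrumMatrix,
    n_boot: int = 25,
    classes=(1, 4),
    percentile_p: bool = False,
) -> pd.DataFrame:
    """Pooled bootstrap mean/variance and p-value per spectral variable.

    Returns a DataFrame with columns ``ppm, beta_mean, beta_var, p`` (one
    row per variable, in axis order).  ``percentile_p`` switches to a
    sign-flip percentile p-value from the pooled bootstrap distribution
    (kept in memory; intended for sensitivity analysis at modest sizes).
    """
    positive, negative = classes
    sub = matrix.select_where(diet=list(classes))
    ann = sub.annotation_frame()
    diets = list(ann["diet"])
    subjects = list(ann["subject_id"].astype(str))
    rows_by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(subjects):
        rows_by_subject.setdefault(s, []).append(i)

    cfg = ensemble.config
    p_vars = sub.n_points
    count = 0
    running_sum = np.zeros(p_vars)
    running_sq = np.zeros(p_vars)
    all_betas = [] if percentile_p else None
    n_redraws = 0
    for m_idx, model in enumerate(ensemble.models):
        if cfg.split_unit != "subject":
            train_subjects = sorted(
                {subjects[sub.sample_ids.index(u)] for u in model.train_units}
            )
        else:
            train_subjects = list(model.train_units)
        rng = substream(cfg.seed, "bootstrap", m_idx)
        for _ in range(n_boot):
            for _attempt in range(100):
                picked = rng.choice(len(train_subjects), size=len(train_subjects),
                                    replace=True)
                rows, labels, subj = [], [], []
                for j, k in enumerate(picked):
                    s = train_subjects[k]
                    for r in rows_by_subject[s]:
                        rows.append(r)
                        labels.append(diets[r])
                        # duplicated subjects become distinct pseudo-subjects
                        subj.append(f"{s}#{j}")
                if positive in labels and negative in labels:
                    break
                n_redraws += 1
            else:
                raise RuntimeError("bootstrap resample never contained both classes")
            fit = fit_plsda(
                sub.intensities[rows], labels, subjects=subj,
                positive_class=positive, negative_class=negative,
                n_components=cfg.n_components, mode=cfg.scaling_mode,
                subject_centring=cfg.subject_centring,
            )
            running_sum += fit.beta
            running_sq += fit.beta**2
            count += 1
            if all_betas is not None:
                all_betas.append(fit.beta)

    beta_mean = running_sum / count
    beta_var = running_sq / count - beta_mean**2
    beta_var = np.maximum(beta_var, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta_mean) / np.sqrt(beta_var)
    p = 2.0 * norm.sf(z)
    degenerate = beta_var == 0.0
    p[degenerate & (beta_mean == 0.0)] = 1.0
    p[degenerate & (beta_mean != 0.0)] = _P_FLOOR
    if all_betas is not None:
        B = np.array(all_betas)
        exceed = np.mean(np.abs(B - beta_mean) >= np.abs(beta_mean), axis=0)
        p = np.where(degenerate, p, np.maximum(exceed, 1.0 / count))
    p = np.clip(p, _P_FLOOR, 1.0)

    table = pd.DataFrame(
        {
            "ppm": sub.ppm,
            "beta_mean": beta_mean,
            "beta_var": beta_var,
            "p": p,
        }
    )
    table.attrs["n_bootstrap_draws"] = count
    table.attrs["n_class_redraws"] = n_redraws
    return table


def fdr_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` on the sorted p-values, capped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def attach_qvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``q`` and the Manhattan statistic ``signed_logq`` to a
    significance table."""
    out = table.copy()
    q = fdr_qvalues(out["p"].to_numpy())
    out["q"] = q
    sign = np.sign(out["beta_mean"].to_numpy())
    out["signed_logq"] = -np.log10(np.maximum(q, _P_FLOOR)) * sign
    return out


def variable_map(
    signatures: list[MetaboliteSignature] | list[dict],
    ppm: np.ndarray,
) -> dict[str, np.ndarray]:
    """Map each metabolite to its peak-apex variable indices.

    A metabolite's variables are the grid points within one half-width of
    each of its peak positions; on grids coarser than the peak width, the
    nearest grid point is used so no peak maps to an empty set.
    """
    ppm = np.asarray(ppm, dtype=float)
    mapping: dict[str, np.ndarray] = {}
    for sig in signatures:
        if isinstance(sig, dict):
            name, peaks = sig["name"], sig["peaks"]
        else:
            name, peaks = sig.name, sig.peaks
        idx: set[int] = set()
        for pos, width, _rel in peaks:
            within = np.nonzero(np.abs(ppm - pos) <= width)[0]
            if within.size == 0:
                nearest = int(np.argmin(np.abs(ppm - pos)))
                if abs(ppm[nearest] - pos) <= 5 * width:
                    within = np.array([nearest])
            idx.update(int(i) for i in within)
        mapping[name] = np.array(sorted(idx), dtype=int)
    return mapping


def call_metabolites(
    table: pd.DataFrame,
    var_map: dict[str, np.ndarray],
    q_cutoff: float = 0.01,
) -> list[MetaboliteCall]:
    """Aggregate variable significance to metabolite-level calls.

    A metabolite is called when at least half of its peak-apex variables
    have ``q <= q_cutoff`` with a common coefficient sign; the direction
    follows that sign (+ -> diet-1-elevated under the +1 = diet 1 encoding).
    """
    if not var_map:
        raise ValueError("empty variable-to-metabolite map")
    q = table["q"].to_numpy()
    sign = np.sign(table["beta_mean"].to_numpy())
    calls = []
    for name, idx in var_map.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            calls.append(MetaboliteCall(name, None, 0, 0, False))
            continue
        sig_mask = q[idx] <= q_cutoff
        n_pos = int(np.sum(sig_mask & (sign[idx] > 0)))
        n_neg = int(np.sum(sig_mask & (sign[idx] < 0)))
        n_major = max(n_pos, n_neg)
        called = n_major >= 0.5 * idx.size and n_major >= 1
        direction = None
        if called:
            direction = "diet1-elevated" if n_pos >= n_neg else "diet4-elevated"
        calls.append(
            MetaboliteCall(
                metabolite=name,
                direction=direction,
                n_significant_variables=n_major,
                n_variables=int(idx.size),
                called=bool(called),
            )
        )
    return calls
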