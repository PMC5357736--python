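"""Spectral region exclusion and Probabilistic Quotient Normalization (PQN).

PQN removes multiplicative dilution (osmolality) differences between urine
samples: each spectrum is divided by the median ratio of its intensities to
a reference spectrum — here, as in the originating trial design, the median
spectrum of the two extreme diets combined.  External cohorts are normalised
to the *training* reference, never to their own median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectrumMatrix

__all__ = [
    "NormalizationRecord",
    "exclude_regions",
    "median_reference",
    "pqn_normalise",
    "normalise_cohort",
    "DEFAULT_EXCLUDED_REGIONS",
]

#: Water presaturation region excluded by default before any normalisation.
DEFAULT_EXCLUDED_REGIONS = [(4.5, 5.0)]

#: Quotients use only variables where the reference exceeds this fraction of
#: its maximum: the dilution estimate should rest on well-quantified,
#: predominantly diet-stable signal (creatinine/urea-class resonances), not
#: on near-baseline points whose ratios are noise- and tail-dominated and
#: not on the wings of food-responsive peaks, which drag the ratio median
#: with diet (compositional closure).
DEFAULT_ELIGIBLE_FLOOR = 0.10


@dataclass
class NormalizationRecord:
    """Provenance of a PQN pass: the reference, per-sample quotients and the
    ppm regions removed before normalisation."""

    reference: np.ndarray
    quotients: dict[str, float]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    eligible_floor: float = DEFAULT_ELIGIBLE_FLOOR

    def __post_init__(self) -> None:
        q = np.array(list(self.quotients.values()), dtype=float)
        if q.size and not np.all(np.isfinite(q) & (q > 0)):
            raise ValueError("quotients must be positive and finite")


def exclude_regions(
    matrix: SpectrumMatrix, regions: list[tuple[float, float]]
) -> SpectrumMatrix:
    """Drop every spectral variable whose ppm lies in any closed region."""
    if not regions:
        return matrix.copy()
    lo_axis, hi_axis = matrix.ppm[0], matrix.ppm[-1]
    keep = np.ones(matrix.n_points, dtype=bool)
    for low, high in regions:
        if low > high:
            raise ValueError(f"region low {low} > high {high}")
        if high < lo_axis or low > hi_axis:
            raise ValueError(
                f"region ({low}, {high}) outside axis [{lo_axis}, {hi_axis}]"
            )
        keep &= ~((matrix.ppm >= low) & (matrix.ppm <= high))
    if not keep.any():
        raise ValueError("exclusion would remove every spectral variable")
    return SpectrumMatrix(
        list(matrix.sample_ids),
        matrix.ppm[keep],
        matrix.intensities[:, keep].copy(),
        matrix.annotations,
    )


def median_reference(matrix: SpectrumMatrix, sample_ids) -> np.ndarray:
    """Per-variable median spectrum over a sample subset.

    Even subset sizes use the midpoint of the two central order statistics.
    """
    ids = list(sample_ids)
    if not ids:
        raise ValueError("reference subset must be nonempty")
    sub = matrix.subset_samples(ids)
    return np.median(sub.intensities, axis=0)


def pqn_normalise(
    matrix: SpectrumMatrix,
    reference: np.ndarray,
    eligible_floor: float = DEFAULT_ELIGIBLE_FLOOR,
    excluded_regions: list[tuple[float, float]] | None = None,
) -> tuple[SpectrumMatrix, NormalizationRecord]:
    """Divide each sample by its median intensity ratio to ``reference``.

    Only variables where the reference exceeds ``eligible_floor`` times its
    maximum enter the quotient median.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (matrix.n_points,):
        raise ValueError("reference length must match the spectral axis")
    ref_max = np.max(reference)
    if not (np.isfinite(ref_max) and ref_max > 0):
        raise ValueError("reference must be positive somewhere")
    eligible = reference > eligible_floor * ref_max
    quotients = {}
    out = np.empty_like(matrix.intensities)
    for i, sid in enumerate(matrix.sample_ids):
        ratios = matrix.intensities[i, eligible] / reference[eligible]
        q = float(np.median(ratios))
        if not (np.isfinite(q) and q > 0):
            raise ValueError(f"sample {sid}: nonpositive PQN quotient {q}")
        quotients[sid] = q
        out[i] = matrix.intensities[i] / q
    record = NormalizationRecord(
        reference=reference,
        quotients=quotients,
        excluded_regions=list(excluded_regions or []),
        eligible_floor=eligible_floor,
    )
    return matrix.with_intensities(out), record


def normalise_cohort(
    matrix: SpectrumMatrix,
    reference_diets=(1, 4),
    excluded_regions: list[tuple[float, float]] | None = None,
    eligible_floor: float = DEFAULT_ELIGIBLE_FLOOR,
    reference: np.ndarray | None = None,
) -> tuple[SpectrumMatrix, NormalizationRecord]:
    """Region exclusion + PQN against the extreme-diet median reference.

    When ``reference`` is given (projection of an external cohort), it is
    reused as-is and ``reference_diets`` is ignored; otherwise the reference
    is the per-variable median over all samples of the reference diets.
    """
    regions = DEFAULT_EXCLUDED_REGIONS if excluded_regions is None else excluded_regions
    trimmed = exclude_regions(matrix, regions)
    if reference is None:
        ann = trimmed.annotation_frame()
        ids = [
            s for s, d in zip(trimmed.sample_ids, ann["diet"])
            if d in set(reference_diets)
        ]
        reference = median_reference(trimmed, ids)
    normalised, record = pqn_normalise(
        trimmed, reference, eligible_floor=eligible_floor, excluded_regions=regions
    )
    return normalised, record
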