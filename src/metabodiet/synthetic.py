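"""Seeded synthetic urinary 1H-NMR cohort generator.

Emulates the statistical structure of a controlled crossover feeding trial:
``n_subjects`` volunteers each consume every diet (default four, labelled
1..4 from most to least concordant with healthy-eating guidance) for
``days`` days, and each subject x diet x day urine sample yields a spectrum
digitised over delta 0.5-9.5 ppm.

Each metabolite is a :class:`MetaboliteSignature`: a handful of Lorentzian
peaks plus per-diet multiplicative concentration effects and log-normal
between-subject / within-subject (day-to-day) variability.  The default
library plants 28 diet-discriminant metabolites - 19 excreted more under
diet 1 (e.g. hippurate, tartrate, TMAO) and 9 more under diet 4 (e.g.
carnitine, phenylacetylglutamine) - among a configurable number of
non-discriminant "nuisance" metabolites, mirroring the discriminant set the
crossover trial recovers.  Sample spectra additionally receive additive
Gaussian baseline noise and a log-normal multiplicative dilution factor
(urine osmolality), both retained as ground truth so that normalisation and
inference can be validated against the planted values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .spectra import SpectrumMatrix

__all__ = [
    "MetaboliteSignature",
    "CohortDesign",
    "signature_library",
    "default_signature_library",
    "render_spectrum",
    "signature_basis",
    "generate_cohort",
    "substream",
]

#: Water presaturation region left peak-free by the generator so the default
#: preprocessing exclusion removes nothing informative.
WATER_REGION = (4.5, 5.0)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, order-independent random substream of a master seed.

    Each distinct key tuple yields an independent deterministic stream, so
    e.g. adding subjects to a design does not perturb the draws of existing
    subjects.
    """
    words = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        words.append(zlib.crc32(repr(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass
class MetaboliteSignature:
    """A named metabolite's spectral and cohort-level generative parameters.

    ``peaks`` are ``(position_ppm, half_width_ppm, relative_intensity)``
    triples; ``diet_effect`` maps each diet label to the multiplicative mean
    concentration under that diet (identical across diets for nuisance
    metabolites).  ``cv_between_subject`` and ``cv_within`` are coefficients
    of variation of the log-normal subject and day effects.
    """

    name: str
    peaks: list[tuple[float, float, float]]
    diet_effect: dict
    cv_between_subject: float = 0.0
    cv_within: float = 0.0

    def validate(self, design: "CohortDesign") -> None:
        lo, hi = design.ppm_range
        for pos, width, rel in self.peaks:
            if not (lo <= pos <= hi):
                raise ValueError(
                    f"{self.name}: peak at {pos} ppm outside axis [{lo}, {hi}]"
                )
            if width <= 0:
                raise ValueError(f"{self.name}: nonpositive peak width")
            if rel < 0:
                raise ValueError(f"{self.name}: negative relative intensity")
        total = sum(rel for _, _, rel in self.peaks)
        if not (np.isfinite(total) and total > 0):
            raise ValueError(f"{self.name}: relative intensities must sum > 0")
        if set(self.diet_effect) != set(design.diets):
            raise ValueError(f"{self.name}: diet_effect must cover all diets")
        if self.cv_between_subject < 0 or self.cv_within < 0:
            raise ValueError(f"{self.name}: negative coefficient of variation")

    @property
    def is_discriminant(self) -> bool:
        effects = list(self.diet_effect.values())
        return max(effects) / min(effects) > 1.0 + 1e-12

    def direction(self, diets) -> str | None:
        """'diet1-elevated', 'diet4-elevated' or None for flat signatures."""
        first, last = self.diet_effect[diets[0]], self.diet_effect[diets[-1]]
        if first > last * (1 + 1e-12):
            return "diet1-elevated"
        if last > first * (1 + 1e-12):
            return "diet4-elevated"
        return None


@dataclass
class CohortDesign:
    """Crossover-trial layout and noise levels of a synthetic cohort."""

    n_subjects: int = 19
    diets: tuple = (1, 2, 3, 4)
    days: int = 3
    n_points: int = 16000
    ppm_range: tuple[float, float] = (0.5, 9.5)
    baseline_noise_sd: float = 0.02
    dilution_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.ppm_range[0] >= self.ppm_range[1]:
            raise ValueError("ppm_range low must be < high")
        if self.n_subjects < 1 or self.days < 1 or len(self.diets) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.baseline_noise_sd < 0 or self.dilution_log_sd < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def ppm(self) -> np.ndarray:
        return np.linspace(self.ppm_range[0], self.ppm_range[1], self.n_points)


# ---------------------------------------------------------------------------
# Signature library
# ---------------------------------------------------------------------------

# Real urinary markers named for readability (diet-1-elevated first).
_DIET1_NAMES = [
    "hippurate", "tartrate", "TMAO", "proline_betaine", "4-hydroxyhippurate",
    "S-methyl-L-cysteine-sulfoxide", "1-methylhistidine", "3-methylhistidine",
    "dimethylamine",
]
_DIET4_NAMES = ["carnitine", "phenylacetylglutamine", "creatine"]
# Diet-stable background metabolites; creatinine and urea dominate real
# urine spectra and anchor the PQN quotient.
_NUISANCE_NAMES = ["creatinine", "urea", "citrate", "glycine", "alanine",
                   "lactate"]


def signature_library(
    n_diet1_elevated: int = 19,
    n_diet4_elevated: int = 9,
    n_nuisance: int = 60,
    diets: tuple = (1, 2, 3, 4),
    effect_ratio_range: tuple[float, float] = (2.0, 4.0),
    cv_between_subject: float = 0.4,
    cv_within: float = 0.15,
    nuisance_cv_between: float = 0.25,
    nuisance_cv_within: float = 0.10,
    peak_width: float = 0.002,
    min_peak_separation: float = 0.03,
    disc_peak_range: tuple[int, int] = (1, 2),
    nuisance_peak_range: tuple[int, int] = (3, 4),
    library_seed: int = 20170301,
) -> list[MetaboliteSignature]:
    """Deterministically build a metabolite signature library.

    Discriminant signatures get a diet-effect ratio drawn uniformly from
    ``effect_ratio_range`` between the extreme diets, graded log-linearly
    across the diet sequence (so intermediate diets sit between the
    extremes).  Nuisance signatures have identical diet_effect everywhere.
    Peak apexes are placed on a shuffled grid outside the water region with
    at least ``min_peak_separation`` ppm between any two apexes, keeping
    neighbouring metabolites spectrally resolvable.

    Concentration levels mirror real urine composition: the diet-stable
    background metabolites have right-skewed levels (log-uniform 1-5,
    with a dominant creatinine-like species at 10 and a broad urea-like
    resonance) and carry more peaks per metabolite (multiplets) than the
    lower-concentration diet-discriminant food metabolites (base level
    0.3-1).  This keeps the PQN dilution quotient anchored on diet-stable
    signal, as it is in practice.
    """
    rng = np.random.default_rng(library_seed)
    n_total = n_diet1_elevated + n_diet4_elevated + n_nuisance

    lo, hi = 0.6, 9.4
    slots = []
    x = lo
    while x <= hi:
        if not (WATER_REGION[0] - min_peak_separation < x < WATER_REGION[1]
                + min_peak_separation):
            slots.append(round(x, 4))
        x += min_peak_separation
    slots = list(rng.permutation(slots))

    n_disc = n_diet1_elevated + n_diet4_elevated
    n_peaks = np.concatenate([
        rng.integers(disc_peak_range[0], disc_peak_range[1] + 1, size=n_disc),
        rng.integers(nuisance_peak_range[0], nuisance_peak_range[1] + 1,
                     size=n_nuisance),
    ])
    if int(n_peaks.sum()) > len(slots):
        raise ValueError(
            "not enough resolvable apex positions: reduce metabolites/peaks "
            "or min_peak_separation"
        )

    names = []
    names += _DIET1_NAMES[:n_diet1_elevated]
    names += [f"d1_marker_{i:02d}" for i in range(len(names), n_diet1_elevated)]
    d4 = _DIET4_NAMES[:n_diet4_elevated]
    d4 += [f"d4_marker_{i:02d}" for i in range(len(d4), n_diet4_elevated)]
    names += d4
    nuis = _NUISANCE_NAMES[:n_nuisance]
    nuis += [f"nuisance_{i:02d}" for i in range(len(nuis), n_nuisance)]
    names += nuis

    k = len(diets)
    grades = np.linspace(1.0, 0.0, k)  # log-linear from diet 1 down to diet 4
    sigs: list[MetaboliteSignature] = []
    slot_iter = iter(slots)
    for i, name in enumerate(names):
        peaks = []
        width = 0.03 if name == "urea" else peak_width  # urea: broad singlet
        for _ in range(1 if name == "urea" else int(n_peaks[i])):
            pos = next(slot_iter)
            rel = float(rng.uniform(0.4, 1.0))
            peaks.append((float(pos), width, rel))
        if i < n_diet1_elevated:
            ratio = float(rng.uniform(*effect_ratio_range))
            level = float(rng.uniform(0.3, 1.0))
            effects = {d: float(level * ratio ** g) for d, g in zip(diets, grades)}
        elif i < n_diet1_elevated + n_diet4_elevated:
            ratio = float(rng.uniform(*effect_ratio_range))
            level = float(rng.uniform(0.3, 1.0))
            effects = {d: float(level * ratio ** (1.0 - g))
                       for d, g in zip(diets, grades)}
        else:
            level = float(10.0 ** rng.uniform(0.0, np.log10(5.0)))
            if name == "creatinine":
                level = 10.0
            elif name == "urea":
                level = 6.0
            effects = {d: level for d in diets}
        discriminant = i < n_disc
        sigs.append(
            MetaboliteSignature(
                name=name,
                peaks=peaks,
                diet_effect=effects,
                cv_between_subject=(cv_between_subject if discriminant
                                    else nuisance_cv_between),
                cv_within=cv_within if discriminant else nuisance_cv_within,
            )
        )
    return sigs


def default_signature_library(n_nuisance: int = 60) -> list[MetaboliteSignature]:
    """The default 28-discriminant library: 19 diet-1-elevated, 9
    diet-4-elevated, plus ``n_nuisance`` flat metabolites."""
    return signature_library(19, 9, n_nuisance)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _lorentzian(x: np.ndarray, position: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + ((x - position) / width) ** 2)


def signature_basis(
    signatures: list[MetaboliteSignature], ppm: np.ndarray
) -> np.ndarray:
    """Unit-concentration spectra, one row per signature (n_metab x n_points)."""
    basis = np.zeros((len(signatures), len(ppm)))
    for i, sig in enumerate(signatures):
        for pos, width, rel in sig.peaks:
            basis[i] += rel * _lorentzian(ppm, pos, width)
    return basis


def render_spectrum(
    signatures: list[MetaboliteSignature],
    concentrations,
    design: CohortDesign,
) -> np.ndarray:
    """Noise-free spectrum of a mixture: sum of Lorentzian peak shapes.

    Each peak contributes ``concentration * relative_intensity *
    L(x; position, width)`` with ``L(x) = 1 / (1 + ((x - position)/width)^2)``;
    contributions add linearly.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (len(signatures),):
        raise ValueError(
            f"{len(signatures)} signatures but {conc.shape} concentrations"
        )
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    return conc @ signature_basis(signatures, design.ppm)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal: cv^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv**2)))


def generate_cohort(
    design: CohortDesign,
    signatures: list[MetaboliteSignature] | None = None,
    collection: str = "24h",
):
    """Generate a full crossover cohort.

    Returns ``(SpectrumMatrix, annotations DataFrame, ground_truth dict)``.
    Per subject x diet x day sample, the planted concentration of metabolite
    ``m`` is ``diet_effect[diet] * subject_effect * day_effect`` with
    log-normal subject/day effects (sigma from the respective CV).  The
    spectrum is the Lorentzian rendering plus additive Gaussian baseline
    noise, all multiplied by a log-normal dilution factor.  The same master
    seed reproduces the cohort bit-identically; per-subject and per-sample
    substreams are named, so enlarging the design leaves existing samples
    unchanged.
    """
    if signatures is None:
        signatures = default_signature_library()
    for sig in signatures:
        sig.validate(design)
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")

    ppm = design.ppm
    basis = signature_basis(signatures, ppm)
    n_metab = len(signatures)
    sigma_b = np.array([_lognormal_sigma(s.cv_between_subject) for s in signatures])
    sigma_w = np.array([_lognormal_sigma(s.cv_within) for s in signatures])

    subj_ids = [f"S{i + 1:02d}" for i in range(design.n_subjects)]
    subject_effect = {
        sid: np.exp(substream(design.seed, "subject", sid).normal(size=n_metab)
                    * sigma_b)
        for sid in subj_ids
    }

    sample_ids, rows, ann_rows = [], [], []
    conc_rows = []
    for sid in subj_ids:
        for diet in design.diets:
            diet_eff = np.array([s.diet_effect[diet] for s in signatures])
            for day in range(1, design.days + 1):
                rng = substream(design.seed, "sample", sid, diet, day, collection)
                day_effect = np.exp(rng.normal(size=n_metab) * sigma_w)
                conc = diet_eff * subject_effect[sid] * day_effect
                spectrum = conc @ basis
                if design.baseline_noise_sd > 0:
                    spectrum = spectrum + rng.normal(
                        scale=design.baseline_noise_sd, size=design.n_points
                    )
                else:
                    rng.normal(size=design.n_points)  # keep stream alignment
                if design.dilution_log_sd > 0:
                    dilution = float(
                        np.exp(rng.normal() * design.dilution_log_sd)
                    )
                else:
                    rng.normal()
                    dilution = 1.0
                sample_id = f"{sid}_D{diet}_day{day}"
                sample_ids.append(sample_id)
                rows.append(spectrum * dilution)
                conc_rows.append(conc)
                ann_rows.append(
                    dict(
                        sample_id=sample_id,
                        subject_id=sid,
                        diet=diet,
                        day=day,
                        collection=collection,
                        dilution_factor=dilution,
                    )
                )

    annotations = pd.DataFrame(ann_rows).set_index("sample_id")
    matrix = SpectrumMatrix(sample_ids, ppm, np.array(rows), annotations)
    ground_truth = {
        "design": asdict(design),
        "metabolites": names,
        "signatures": [
            {
                "name": s.name,
                "peaks": [list(p) for p in s.peaks],
                "diet_effect": {str(k): v for k, v in s.diet_effect.items()},
                "direction": s.direction(design.diets),
            }
            for s in signatures
        ],
        "diet1_elevated": [
            s.name for s in signatures if s.direction(design.diets) == "diet1-elevated"
        ],
        "diet4_elevated": [
            s.name for s in signatures if s.direction(design.diets) == "diet4-elevated"
        ],
        "concentrations": {
            sid: [float(c) for c in conc]
            for sid, conc in zip(sample_ids, conc_rows)
        },
        "dilution_factors": {
            r["sample_id"]: r["dilution_factor"] for r in ann_rows
        },
    }
    return matrix, annotations, ground_truth
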