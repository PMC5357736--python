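"""Generator contracts: library composition, Lorentzian rendering, cohort
structure, determinism and noise degeneracies."""

import numpy as np
import pytest

import metabodiet as md
from metabodiet.synthetic import WATER_REGION, signature_basis


class TestSignatureLibrary:
    def test_default_discriminant_composition(self):
        sigs = md.default_signature_library()
        diets = (1, 2, 3, 4)
        up = [s for s in sigs if s.direction(diets) == "diet1-elevated"]
        down = [s for s in sigs if s.direction(diets) == "diet4-elevated"]
        flat = [s for s in sigs if s.direction(diets) is None]
        assert len(up) == 19
        assert len(down) == 9
        assert len(flat) == 60

    def test_nuisance_effects_flat(self):
        for s in md.default_signature_library():
            if not s.is_discriminant:
                effects = list(s.diet_effect.values())
                assert max(effects) / min(effects) == 1.0

    def test_discriminant_grading_monotone(self):
        """Effects are graded monotonically from diet 1 to diet 4."""
        for s in md.default_signature_library():
            seq = [s.diet_effect[d] for d in (1, 2, 3, 4)]
            if s.direction((1, 2, 3, 4)) == "diet1-elevated":
                assert all(a > b for a, b in zip(seq, seq[1:]))
            elif s.direction((1, 2, 3, 4)) == "diet4-elevated":
                assert all(a < b for a, b in zip(seq, seq[1:]))

    def test_exemplar_marker_names_present(self):
        names = {s.name for s in md.default_signature_library()}
        assert {"hippurate", "carnitine", "tartrate", "TMAO",
                "proline_betaine"} <= names

    def test_no_peaks_in_water_region(self):
        for s in md.default_signature_library():
            for pos, width, _ in s.peaks:
                assert not (WATER_REGION[0] <= pos <= WATER_REGION[1])

    def test_deterministic(self):
        a = md.default_signature_library()
        b = md.default_signature_library()
        assert [s.peaks for s in a] == [s.peaks for s in b]
        assert [s.diet_effect for s in a] == [s.diet_effect for s in b]

    def test_validation_rejects_bad_peaks(self):
        design = md.CohortDesign(n_points=100)
        sig = md.MetaboliteSignature(
            "bad", [(12.0, 0.01, 1.0)], {d: 1.0 for d in (1, 2, 3, 4)}
        )
        with pytest.raises(ValueError, match="outside axis"):
            sig.validate(design)


class TestRenderSpectrum:
    def test_zero_concentrations_zero_spectrum(self):
        design = md.CohortDesign(n_points=200)
        sigs = md.signature_library(1, 1, 2, peak_width=0.05,
                                    min_peak_separation=0.5)
        out = md.render_spectrum(sigs, np.zeros(len(sigs)), design)
        assert np.all(out == 0)

    def test_single_peak_closed_form(self):
        """Intensity at the nearest grid point equals the Lorentzian value."""
        design = md.CohortDesign(n_points=1001, ppm_range=(0.5, 9.5))
        sig = md.MetaboliteSignature(
            "one", [(3.00, 0.005, 1.0)], {d: 1.0 for d in (1, 2, 3, 4)}
        )
        spectrum = md.render_spectrum([sig], [2.0], design)
        ppm = design.ppm
        i = int(np.argmin(np.abs(ppm - 3.00)))
        expected = 2.0 / (1.0 + ((ppm[i] - 3.00) / 0.005) ** 2)
        assert spectrum[i] == pytest.approx(expected, rel=1e-12)

    def test_linearity_and_doubling(self):
        design = md.CohortDesign(n_points=400)
        sigs = md.signature_library(2, 1, 3, peak_width=0.05,
                                    min_peak_separation=0.4)
        rng = np.random.default_rng(0)
        conc = rng.uniform(0.5, 2.0, size=len(sigs))
        mix = md.render_spectrum(sigs, conc, design)
        singles = sum(
            md.render_spectrum(
                sigs, np.eye(len(sigs))[i] * conc[i], design
            )
            for i in range(len(sigs))
        )
        np.testing.assert_allclose(mix, singles, rtol=1e-12)
        np.testing.assert_allclose(
            md.render_spectrum(sigs, 2 * conc, design), 2 * mix, rtol=1e-12
        )

    def test_rejects_negative_and_mismatched(self):
        design = md.CohortDesign(n_points=100)
        sigs = md.signature_library(1, 0, 1, peak_width=0.05,
                                    min_peak_separation=0.5)
        with pytest.raises(ValueError):
            md.render_spectrum(sigs, [-1.0, 1.0], design)
        with pytest.raises(ValueError):
            md.render_spectrum(sigs, [1.0], design)


class TestGenerateCohort:
    def test_sample_count_19x4x3(self):
        design = md.CohortDesign(n_subjects=19, days=3, n_points=64, seed=0)
        sigs = md.signature_library(1, 1, 2, peak_width=0.2,
                                    min_peak_separation=0.8)
        matrix, ann, _ = md.generate_cohort(design, sigs)
        assert matrix.n_samples == 19 * 4 * 3
        assert len(ann) == 228
        key = ann.reset_index()[["subject_id", "diet", "day", "collection"]]
        assert not key.duplicated().any()

    def test_same_seed_bit_identical(self, small_cohort):
        again, ann, _ = md.generate_cohort(
            small_cohort["design"], small_cohort["signatures"]
        )
        assert np.array_equal(again.intensities,
                              small_cohort["matrix"].intensities)

    def test_zero_dilution_sd_gives_unit_factors(self):
        design = md.CohortDesign(n_subjects=2, days=1, n_points=64,
                                 dilution_log_sd=0.0, seed=3)
        sigs = md.signature_library(1, 0, 1, peak_width=0.2,
                                    min_peak_separation=0.8)
        _, ann, truth = md.generate_cohort(design, sigs)
        assert set(truth["dilution_factors"].values()) == {1.0}
        assert set(ann["dilution_factor"]) == {1.0}

    def test_noise_free_same_diet_identical(self):
        """With all CVs and noise zero, all samples of a diet coincide."""
        design = md.CohortDesign(
            n_subjects=3, days=2, n_points=300, seed=5,
            baseline_noise_sd=0.0, dilution_log_sd=0.0,
        )
        sigs = md.signature_library(
            2, 1, 2, cv_between_subject=0.0, cv_within=0.0,
            nuisance_cv_between=0.0, nuisance_cv_within=0.0,
            peak_width=0.05, min_peak_separation=0.4,
        )
        matrix, ann, _ = md.generate_cohort(design, sigs)
        for diet in (1, 2, 3, 4):
            rows = matrix.intensities[(ann["diet"] == diet).to_numpy()]
            assert np.ptp(rows, axis=0).max() == 0.0

    def test_dilution_is_exact_scalar_multiplier(self, small_cohort):
        """Dividing by the planted factor reproduces the undiluted cohort."""
        design = small_cohort["design"]
        undiluted_design = md.CohortDesign(
            **{**design.__dict__, "dilution_log_sd": 0.0}
        )
        undiluted, _, _ = md.generate_cohort(
            undiluted_design, small_cohort["signatures"]
        )
        factors = small_cohort["annotations"]["dilution_factor"].to_numpy()
        np.testing.assert_allclose(
            small_cohort["matrix"].intensities / factors[:, None],
            undiluted.intensities,
            rtol=1e-12,
        )

    def test_planted_directions_match_design(self, small_cohort):
        truth = small_cohort["truth"]
        assert len(truth["diet1_elevated"]) == 4
        assert len(truth["diet4_elevated"]) == 2
        for entry in truth["signatures"]:
            if entry["name"] in truth["diet1_elevated"]:
                assert entry["direction"] == "diet1-elevated"

    def test_adding_subjects_preserves_existing_samples(self):
        sigs = md.signature_library(1, 1, 2, peak_width=0.2,
                                    min_peak_separation=0.8)
        base = md.CohortDesign(n_subjects=2, days=1, n_points=64, seed=9)
        bigger = md.CohortDesign(n_subjects=3, days=1, n_points=64, seed=9)
        m1, _, _ = md.generate_cohort(base, sigs)
        m2, _, _ = md.generate_cohort(bigger, sigs)
        common = [s for s in m1.sample_ids]
        np.testing.assert_array_equal(
            m1.intensities, m2.subset_samples(common).intensities
        )


def test_basis_matches_render():
    design = md.CohortDesign(n_points=200)
    sigs = md.signature_library(1, 1, 2, peak_width=0.1,
                                min_peak_separation=0.6)
    basis = signature_basis(sigs, design.ppm)
    conc = np.array([1.0, 2.0, 0.5, 3.0])
    np.testing.assert_allclose(
        conc @ basis, md.render_spectrum(sigs, conc, design), rtol=1e-12
    )
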