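"""Envelope extraction, RIA/LR mixture fitting, chi-squared validation, and
the labeled-peptide detection gate."""

import numpy as np
import pytest
from scipy import stats

from sipquant import (
    ObservedSpectrum,
    PeptideIdentification,
    PeptideIon,
    chi_squared_fit,
    composition_of,
    detect_labeled_peptides,
    estimate_ria_lr,
    extract_envelope,
    heavy_isotopologue_mz,
    isotope_pattern,
    simulate_spectrum,
)
from sipquant.constants import NATURAL_13C
from sipquant.proteinsip import envelope_k_max


def spectrum_from_pattern(ion, pattern, scale=1e5):
    mz = np.array([heavy_isotopologue_mz(ion, int(k)) for k in pattern.k])
    return ObservedSpectrum(mz=mz, intensity=pattern.abundances * scale)


class TestExtractEnvelope:
    def test_round_trip_natural_pattern(self, vvn_ion, vvn_comp):
        pat = isotope_pattern(vvn_comp)
        spec = spectrum_from_pattern(vvn_ion, pat)
        env = extract_envelope(spec, vvn_ion, k_max=int(pat.k[-1]))
        assert np.allclose(env, pat.as_vector() * 1e5)

    def test_empty_spectrum_gives_zeros(self, vvn_ion):
        spec = ObservedSpectrum(mz=np.array([]), intensity=np.array([]))
        env = extract_envelope(spec, vvn_ion, k_max=10)
        assert env.shape == (11,) and not env.any()

    def test_simulated_modal_k_preserved(self, vvn_ion, vvn_comp):
        spec = simulate_spectrum(vvn_ion, ria=0.20, lr=1.0, depth_counts=10**5, seed=11)
        env = extract_envelope(spec, vvn_ion, k_max=vvn_comp.n_C)
        assert int(np.argmax(env)) == isotope_pattern(vvn_comp, 0.20).modal_k

    def test_overlapping_windows_rejected(self, vvn_ion):
        spec = ObservedSpectrum(mz=np.array([500.0]), intensity=np.array([1.0]))
        with pytest.raises(ValueError, match="smaller"):
            extract_envelope(spec, vvn_ion, k_max=5, ppm=600)

    def test_peaks_outside_window_ignored(self, vvn_ion):
        mz0 = heavy_isotopologue_mz(vvn_ion, 0)
        spec = ObservedSpectrum(
            mz=np.array([mz0 - 0.1, mz0, mz0 + 0.1]),
            intensity=np.array([5.0, 7.0, 9.0]),
        )
        env = extract_envelope(spec, vvn_ion, k_max=0, ppm=10)
        assert env[0] == 7.0


class TestEstimateRiaLr:
    def test_noiseless_self_consistency(self, vvn_comp):
        env = isotope_pattern(vvn_comp, 0.20).as_vector()
        est = estimate_ria_lr(env, vvn_comp)
        assert est.ria == pytest.approx(0.20, abs=0.005)
        assert est.lr == pytest.approx(1.0, abs=0.01)
        assert est.correlation >= 0.999

    def test_natural_envelope_not_labeled(self, vvn_comp):
        env = isotope_pattern(vvn_comp).as_vector()
        est = estimate_ria_lr(env, vvn_comp)
        assert est.lr == pytest.approx(0.0, abs=0.01)
        assert not est.is_labeled

    def test_constructed_half_mixture(self, vvn_comp):
        env = 0.5 * isotope_pattern(vvn_comp).as_vector(vvn_comp.n_C)
        env += 0.5 * isotope_pattern(vvn_comp, 0.30).as_vector(vvn_comp.n_C)
        est = estimate_ria_lr(env, vvn_comp)
        assert est.ria == pytest.approx(0.30, abs=0.01)
        assert est.lr == pytest.approx(0.5, abs=0.02)

    def test_all_zero_envelope_is_no_signal(self, vvn_comp):
        est = estimate_ria_lr(np.zeros(20), vvn_comp)
        assert not est.has_signal and not est.is_labeled

    def test_deterministic_for_fixed_input(self, vvn_ion, vvn_comp):
        spec = simulate_spectrum(vvn_ion, 0.2, 0.7, 10**4, seed=5)
        env = extract_envelope(spec, vvn_ion, k_max=vvn_comp.n_C)
        a = estimate_ria_lr(env, vvn_comp)
        b = estimate_ria_lr(env.copy(), vvn_comp)
        assert a == b  # bitwise-identical dataclasses

    @pytest.mark.parametrize("ria", [0.05, 0.10, 0.20, 0.40])
    def test_ria_recovery_median_error(self, vvn_ion, vvn_comp, ria):
        errors = []
        for seed in range(25):
            spec = simulate_spectrum(vvn_ion, ria, 1.0, 10**4, seed=seed)
            env = extract_envelope(spec, vvn_ion, k_max=envelope_k_max(vvn_comp))
            errors.append(abs(estimate_ria_lr(env, vvn_comp).ria - ria))
        assert np.median(errors) <= 0.01

    @pytest.mark.parametrize("lr", [0.25, 0.5, 0.75])
    def test_lr_recovery_median_error(self, vvn_ion, vvn_comp, lr):
        errors = []
        for seed in range(25):
            spec = simulate_spectrum(vvn_ion, 0.2, lr, 10**4, seed=seed)
            env = extract_envelope(spec, vvn_ion, k_max=envelope_k_max(vvn_comp))
            errors.append(abs(estimate_ria_lr(env, vvn_comp).lr - lr))
        assert np.median(errors) <= 0.05

    def test_specificity_no_labeled_calls_on_unlabeled(self, vvn_ion, vvn_comp):
        # unlabeled-only simulations must never pass the labeled gate
        for seed in range(300):
            spec = simulate_spectrum(
                vvn_ion, NATURAL_13C, 0.0, 10**4, seed=seed
            )
            env = extract_envelope(spec, vvn_ion, k_max=envelope_k_max(vvn_comp))
            assert not estimate_ria_lr(env, vvn_comp).is_labeled


class TestChiSquared:
    def test_exact_match_gives_zero(self, vvn_comp):
        pat = isotope_pattern(vvn_comp, 0.2)
        chi2, p = chi_squared_fit(pat.as_vector(), pat)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_three_channel_toy(self):
        expected = np.array([0.2, 0.4, 0.4])
        observed = np.array([0.4, 0.3, 0.3])
        chi2, p = chi_squared_fit(observed, expected)
        # hand arithmetic: (0.2^2/0.2) + (0.1^2/0.4) + (0.1^2/0.4) = 0.25
        assert chi2 == pytest.approx(0.25)
        assert p == pytest.approx(float(stats.chi2.sf(0.25, 2)))

    def test_fewer_than_two_channels_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_fit(np.array([1.0]), np.array([1.0]))

    def test_low_abundance_channels_floored_out(self):
        expected = np.array([0.5, 0.5, 1e-6])
        observed = np.array([0.5, 0.5, 10.0])  # junk lands on a floored channel
        chi2, _ = chi_squared_fit(observed, expected)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_pvalues_uniform_under_true_model(self, vvn_comp, rng):
        # Poisson/multinomial resampling of the true pattern: p ~ U(0,1)
        pat = isotope_pattern(vvn_comp)
        vec = pat.as_vector()
        keep = vec / vec.sum() >= 1e-4
        probs = vec / vec.sum()
        pvals = []
        for _ in range(400):
            counts = rng.multinomial(10**5, probs)
            _, p = chi_squared_fit(counts.astype(float), vec)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestDetectLabeledPeptides:
    def make_cohort(self, n_labeled, n_unlabeled, ria=0.2, seed0=0):
        ids, spectra = [], {}
        peptides = ["VVNAEAGNAR", "ELVISLIVES", "GANDALFGREY"]
        for i in range(n_labeled + n_unlabeled):
            seq = peptides[i % len(peptides)]
            sample = f"s{i}"
            ion = PeptideIon(seq, 2)
            labeled = i < n_labeled
            spec = simulate_spectrum(
                ion,
                ria if labeled else NATURAL_13C,
                1.0 if labeled else 0.0,
                depth_counts=10**4,
                seed=seed0 + i,
            )
            ids.append(PeptideIdentification(seq, 2, sample, (f"prot{i}",)))
            spectra[(sample, seq, 2)] = spec
        return spectra, ids

    def test_all_natural_cohort_yields_empty(self):
        spectra, ids = self.make_cohort(0, 20)
        assert detect_labeled_peptides(spectra, ids) == []

    def test_planted_labeled_recovered_exactly(self):
        spectra, ids = self.make_cohort(5, 50, seed0=100)
        records = detect_labeled_peptides(spectra, ids)
        assert sorted(r.sample for r in records) == [f"s{i}" for i in range(5)]
        for rec in records:
            assert rec.estimate.ria == pytest.approx(0.2, abs=0.02)

    def test_missing_spectrum_skipped_not_fatal(self):
        spectra, ids = self.make_cohort(2, 0)
        ids.append(PeptideIdentification("VVNAEAGNAR", 2, "missing", ()))
        records = detect_labeled_peptides(spectra, ids)
        assert len(records) == 2

    def test_noise_degraded_correlation_excluded(self, vvn_ion):
        # corrupt the envelope with large spurious peaks at channel centers
        # until the fit correlation falls below the 0.8 reporting threshold
        clean = simulate_spectrum(vvn_ion, 0.2, 1.0, 10**4, seed=3)
        rng = np.random.default_rng(9)
        comp = composition_of(vvn_ion)
        excluded = None
        for noise_scale in [0.5, 2.0, 8.0, 32.0]:
            junk_k = rng.choice(np.arange(25), size=10, replace=False)
            mz = np.concatenate(
                [clean.mz, [heavy_isotopologue_mz(vvn_ion, int(k)) + 1e-4 for k in junk_k]]
            )
            inten = np.concatenate(
                [
                    clean.intensity,
                    rng.uniform(0, noise_scale * clean.intensity.max(), size=10),
                ]
            )
            order = np.argsort(mz)
            spec = ObservedSpectrum(mz=mz[order], intensity=inten[order])
            env = extract_envelope(spec, vvn_ion, k_max=envelope_k_max(comp))
            est = estimate_ria_lr(env, comp)
            if est.correlation < 0.8:
                excluded = est
                break
        assert excluded is not None, "noise sweep never broke the correlation gate"
        assert not excluded.is_labeled

    def test_output_sorted_and_deterministic(self):
        spectra, ids = self.make_cohort(4, 4)
        a = detect_labeled_peptides(spectra, ids)
        b = detect_labeled_peptides(dict(reversed(list(spectra.items()))), ids[::-1])
        assert a == b
        keys = [(r.sample, r.sequence, r.charge) for r in a]
        assert keys == sorted(keys)
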