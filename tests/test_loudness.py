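"""Excitation, specific/partial loudness and binaural inhibition contracts."""

import numpy as np
import pytest

from parloud import loudness as ld
from parloud.bands import ThirdOctaveSpectrum
from parloud.loudness import (
    ExcitationPattern,
    SpecificLoudnessPattern,
    binaural_inhibition,
    binaural_loudness,
    diotic_tone_loudness,
    excitation_from_components,
    excitation_from_spectrum,
    integrate_loudness,
    partial_specific_loudness,
    specific_loudness,
)
from parloud.bands import silence


def _tone(consts, level, freq=1000.0):
    return excitation_from_components([freq], [level], consts)


class TestExcitation:
    def test_silence_gives_zero_everywhere(self, consts):
        e = excitation_from_spectrum(silence(), constants=consts)
        assert np.all(e.excitation == 0.0)

    def test_monotone_in_band_level(self, consts):
        lo = _tone(consts, 0.0)
        hi = _tone(consts, 10.0)
        assert np.all(hi.excitation >= lo.excitation)
        peak = np.argmax(hi.excitation)
        assert hi.excitation[peak] > lo.excitation[peak]

    def test_raising_any_band_never_decreases_excitation(self, consts):
        spec = ThirdOctaveSpectrum([250.0, 1000.0, 4000.0], [50.0, 55.0, 45.0])
        base = excitation_from_spectrum(spec, constants=consts)
        louder = ThirdOctaveSpectrum([250.0, 1000.0, 4000.0], [50.0, 65.0, 45.0])
        e2 = excitation_from_spectrum(louder, constants=consts)
        assert np.all(e2.excitation >= base.excitation - 1e-15)

    def test_rejects_extreme_level(self, consts):
        with pytest.raises(ValueError):
            excitation_from_components([1000.0], [125.0], consts)


class TestSpecificLoudness:
    def test_zero_excitation_gives_zero(self, consts):
        e = ExcitationPattern(consts.z, np.zeros_like(consts.z), consts.dz)
        s = specific_loudness(e, consts)
        assert np.all(s.n_prime == 0.0)

    def test_matches_scalar_formula_above_threshold(self, consts):
        # mid-level channel: N' = C[(E G + A)^alpha - A^alpha]
        e_val = 1e5
        i = 60  # a mid-frequency channel
        exc = np.zeros_like(consts.z)
        exc[i] = e_val
        s = specific_loudness(ExcitationPattern(consts.z, exc, consts.dz), consts)
        direct = consts.C * (
            (e_val * consts.G[i] + consts.A[i]) ** consts.alpha[i]
            - consts.A[i] ** consts.alpha[i]
        )
        assert s.n_prime[i] == pytest.approx(direct, rel=1e-12)

    def test_power_law_doubling(self, consts):
        # doubling E well above threshold scales N' by about 2^alpha
        i = 60
        exc = np.zeros_like(consts.z)
        exc[i] = 1e8
        s1 = specific_loudness(ExcitationPattern(consts.z, exc, consts.dz), consts)
        exc2 = exc * 2.0
        s2 = specific_loudness(ExcitationPattern(consts.z, exc2, consts.dz), consts)
        assert s2.n_prime[i] / s1.n_prime[i] == pytest.approx(
            2.0 ** consts.alpha[i], rel=0.01
        )

    def test_strictly_increasing_in_excitation(self, consts):
        evals = np.logspace(0, 9, 40)
        n = [
            specific_loudness(
                ExcitationPattern(
                    consts.z, np.full_like(consts.z, e), consts.dz
                ),
                consts,
            ).n_prime[60]
            for e in evals
        ]
        assert np.all(np.diff(n) > 0)


class TestPartialLoudness:
    def test_no_masker_identity_bit_exact(self, consts):
        et = _tone(consts, 60.0)
        eb = ExcitationPattern(consts.z, np.zeros_like(consts.z), consts.dz)
        p = partial_specific_loudness(et, eb, consts)
        s = specific_loudness(et, consts)
        assert np.array_equal(p.n_prime, s.n_prime)

    def test_masking_monotone_over_level_grid(self, consts):
        et = _tone(consts, 60.0)
        vals = []
        for bg in np.linspace(30.0, 80.0, 20):
            eb = _tone(consts, bg)
            vals.append(integrate_loudness(partial_specific_loudness(et, eb, consts)))
        assert np.all(np.diff(vals) < 0)

    def test_partial_bounded_by_unmasked(self, consts):
        et = _tone(consts, 60.0)
        eb = _tone(consts, 55.0, freq=1250.0)
        p = partial_specific_loudness(et, eb, consts)
        s = specific_loudness(et, consts)
        assert np.all(p.n_prime >= 0.0)
        assert np.all(p.n_prime <= s.n_prime + 1e-15)

    def test_additivity_in_strong_target_limit(self, consts):
        # target 30+ dB above its masked threshold: partial + background
        # recovers the total loudness of the mixture within 5 %
        et = _tone(consts, 90.0)
        eb = _tone(consts, 40.0)
        total = specific_loudness(
            ExcitationPattern(consts.z, et.excitation + eb.excitation, consts.dz),
            consts,
        )
        p_t = partial_specific_loudness(et, eb, consts)
        p_b = SpecificLoudnessPattern(
            consts.z,
            ld._nprime_partial(eb.excitation, et.excitation, consts),
            consts.dz,
        )
        lhs = integrate_loudness(p_t) + integrate_loudness(p_b)
        rhs = integrate_loudness(total)
        assert lhs == pytest.approx(rhs, rel=0.05)

    def test_grid_mismatch_rejected(self, consts):
        et = _tone(consts, 60.0)
        bad = ExcitationPattern(consts.z[:-1], np.zeros(consts.z.size - 1), consts.dz)
        with pytest.raises(ValueError):
            partial_specific_loudness(et, bad, consts)


class TestIntegration:
    def test_zero_pattern_is_zero_sones(self, consts):
        p = SpecificLoudnessPattern(consts.z, np.zeros_like(consts.z), consts.dz)
        assert integrate_loudness(p) == 0.0

    def test_linearity(self, consts):
        rng = np.random.default_rng(7)
        a = SpecificLoudnessPattern(consts.z, rng.random(consts.z.size), consts.dz)
        b = SpecificLoudnessPattern(consts.z, rng.random(consts.z.size), consts.dz)
        assert integrate_loudness(a) + integrate_loudness(b) == pytest.approx(
            integrate_loudness(a + b), rel=1e-12
        )


class TestBinauralInhibition:
    def test_factor_with_silent_contralateral_ear(self, consts):
        # sech(0) = 1 -> factor 2 / 2^P = 2^(1-P)
        f = ld._inhibition_factors(np.array([1.0]), np.array([0.0]), consts.P_binaural)
        assert f[0] == pytest.approx(2.0 ** (1.0 - 1.598), rel=1e-6)

    def test_factor_at_equal_ears(self, consts):
        # direct scalar evaluation at ratio 1
        f = ld._inhibition_factors(np.array([1.0]), np.array([1.0]), consts.P_binaural)
        direct = 2.0 / (1.0 + 1.0 / np.cosh(1.0)) ** 1.598
        assert f[0] == pytest.approx(direct, rel=1e-6)
        assert f[0] == pytest.approx(0.900, abs=1e-3)

    def test_diotic_to_monaural_ratio(self, consts):
        e = _tone(consts, 60.0)
        s = specific_loudness(e, consts)
        zero = SpecificLoudnessPattern(consts.z, np.zeros_like(consts.z), consts.dz)
        diotic = binaural_loudness(s, s, consts)
        monaural = binaural_loudness(s, zero, consts)
        assert diotic / monaural == pytest.approx(1.5, abs=0.1)

    def test_ear_swap_symmetry(self, consts):
        sl = specific_loudness(_tone(consts, 55.0), consts)
        sr = specific_loudness(_tone(consts, 65.0, freq=2000.0), consts)
        il, ir = binaural_inhibition(sl, sr, consts)
        jr, jl = binaural_inhibition(sr, sl, consts)
        np.testing.assert_array_equal(il.n_prime, jl.n_prime)
        np.testing.assert_array_equal(ir.n_prime, jr.n_prime)

    def test_silent_ipsilateral_channel_stays_zero(self, consts):
        s = specific_loudness(_tone(consts, 60.0), consts)
        zero = SpecificLoudnessPattern(consts.z, np.zeros_like(consts.z), consts.dz)
        iz, _ = binaural_inhibition(zero, s, consts)
        assert np.all(iz.n_prime == 0.0)

    def test_negative_input_rejected(self, consts):
        bad = SpecificLoudnessPattern(consts.z, np.full(consts.z.size, -1.0), consts.dz)
        with pytest.raises(ValueError):
            binaural_inhibition(bad, bad, consts)


class TestCalibrationAnchors:
    def test_1khz_40db_is_one_sone(self, consts):
        assert diotic_tone_loudness(1000.0, 40.0, consts) == pytest.approx(
            1.0, rel=0.05
        )

    def test_doubling_per_10db(self, consts):
        n40 = diotic_tone_loudness(1000.0, 40.0, consts)
        n50 = diotic_tone_loudness(1000.0, 50.0, consts)
        n60 = diotic_tone_loudness(1000.0, 60.0, consts)
        assert n50 / n40 == pytest.approx(2.0, rel=0.10)
        assert n60 / n50 == pytest.approx(2.0, rel=0.10)
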