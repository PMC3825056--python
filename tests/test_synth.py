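import numpy as np
import pytest

from heartloc import (
    HeartSoundSpec,
    MixtureSpec,
    ParameterError,
    Signal,
    convolutive_mix,
    make_mixture,
    read_truth_csv,
    synth_heart_sound,
    synth_lung_sound,
    write_truth_csv,
)
from heartloc.synth import (
    FLOWS,
    MIXTURE_TYPES,
    TABLE1_NORM_RANGES,
)

RATE = 8000.0


def spectral_energy_fraction(signal, f_lo, f_hi):
    spectrum = np.abs(np.fft.rfft(signal.samples)) ** 2
    freqs = np.fft.rfftfreq(signal.n, d=1.0 / signal.rate)
    band = (freqs >= f_lo) & (freqs < f_hi)
    return spectrum[band].sum() / spectrum.sum()


class TestSynthHeartSound:
    def test_s1_s2_counting(self):
        spec = HeartSoundSpec(duration_s=4.0, cycle_s=0.8, components=("S1", "S2"))
        _, truth = synth_heart_sound(spec, seed=0)
        assert len(truth.segments) == 10  # 5 cycles x 2 components
        assert truth.labels.count("S1") == 5
        assert truth.labels.count("S2") == 5

    def test_adding_s3_counting(self):
        spec = HeartSoundSpec(duration_s=4.0, components=("S1", "S2", "S3"))
        _, truth = synth_heart_sound(spec, seed=0)
        assert len(truth.segments) == 15

    def test_s1_spectral_centroid_in_band(self):
        spec = HeartSoundSpec(duration_s=4.0, components=("S1",))
        sig, _ = synth_heart_sound(spec, seed=1)
        spectrum = np.abs(np.fft.rfft(sig.samples)) ** 2
        freqs = np.fft.rfftfreq(sig.n, d=1.0 / sig.rate)
        centroid = np.sum(freqs * spectrum) / np.sum(spectrum)
        assert 20.0 <= centroid <= 150.0

    def test_deterministic_per_seed(self):
        spec = HeartSoundSpec(duration_s=2.0)
        a, _ = synth_heart_sound(spec, seed=7)
        b, _ = synth_heart_sound(spec, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_truth_segments_cover_nonzero_support(self):
        spec = HeartSoundSpec(duration_s=2.0)
        sig, truth = synth_heart_sound(spec, seed=2)
        for seg in truth.segments:
            assert np.max(np.abs(sig.samples[seg.start : seg.end])) > 0

    def test_overlapping_components_rejected(self):
        from heartloc.synth import ComponentSpec

        bad = ComponentSpec("S2", center_hz=70, duration_s=0.1, amplitude=1,
                            onset_s=0.05)  # collides with S1 at 0.02-0.14
        spec = HeartSoundSpec(
            duration_s=2.0, components=("S1", "S2"), component_specs=(bad,)
        )
        with pytest.raises(ParameterError, match="overlap"):
            synth_heart_sound(spec, seed=0)

    def test_murmur_adds_high_frequency_energy(self):
        normal, _ = synth_heart_sound(HeartSoundSpec(duration_s=4.0), seed=3)
        abnormal, _ = synth_heart_sound(
            HeartSoundSpec(duration_s=4.0, murmur=True), seed=3
        )
        f_norm = spectral_energy_fraction(normal, 400, 800)
        f_abn = spectral_energy_fraction(abnormal, 400, 800)
        assert f_abn > 10 * max(f_norm, 1e-12)


class TestSynthLungSound:
    def test_energy_concentrated_below_200hz(self):
        ls = synth_lung_sound(duration_s=6.0, seed=0)
        assert spectral_energy_fraction(ls, 0, 200) >= 0.6

    def test_out_of_band_energy_below_1pct(self):
        ls = synth_lung_sound(duration_s=6.0, seed=1)
        assert spectral_energy_fraction(ls, 1800, RATE / 2) < 0.01

    def test_two_seeds_distinct_but_similar_spectra(self):
        a = synth_lung_sound(duration_s=6.0, seed=10)
        b = synth_lung_sound(duration_s=6.0, seed=11)
        assert not np.array_equal(a.samples, b.samples)
        fa = spectral_energy_fraction(a, 0, 200)
        fb = spectral_energy_fraction(b, 0, 200)
        assert fa == pytest.approx(fb, abs=0.05)

    def test_duration_below_breath_period_rejected(self):
        with pytest.raises(ParameterError):
            synth_lung_sound(duration_s=1.0, breath_period_s=3.0)

    def test_wheeze_adds_tonal_component(self):
        normal = synth_lung_sound(duration_s=6.0, seed=5)
        abn = synth_lung_sound(duration_s=6.0, abnormal=True, seed=5)
        f_normal = spectral_energy_fraction(normal, 390, 410)
        f_abn = spectral_energy_fraction(abn, 390, 410)
        assert f_abn > 2 * f_normal


class TestConvolutiveMix:
    def test_b_taps_unit_norm(self):
        hs = Signal(np.random.default_rng(0).standard_normal(8000), RATE)
        ls = Signal(np.random.default_rng(1).standard_normal(8000), RATE)
        for seed in range(10):
            spec = MixtureSpec(flow="medium", mixture_type="normal-normal", seed=seed)
            result = convolutive_mix(hs, ls, spec)
            assert np.linalg.norm(result.b_taps) == pytest.approx(1.0, abs=1e-12)

    def test_a_norm_in_table_cell(self):
        hs = Signal(np.zeros(100) + 1e-3, RATE)
        ls = Signal(np.zeros(100) + 1e-3, RATE)
        for mixture_type in MIXTURE_TYPES:
            for flow in FLOWS:
                lo, hi = TABLE1_NORM_RANGES[mixture_type][flow]
                spec = MixtureSpec(flow=flow, mixture_type=mixture_type, seed=0)
                result = convolutive_mix(hs, ls, spec)
                assert lo <= result.a_norm <= hi
                assert np.linalg.norm(result.a_taps) == pytest.approx(
                    result.a_norm, abs=1e-12
                )

    def test_normal_normal_medium_range(self):
        assert TABLE1_NORM_RANGES["normal-normal"]["medium"] == (0.81, 3.10)

    def test_identity_taps_reduce_to_addition(self, rng):
        hs = Signal(rng.standard_normal(1000), RATE)
        ls = Signal(rng.standard_normal(1000), RATE)
        spec = MixtureSpec(flow="low", mixture_type="normal-normal", seed=0)
        identity = np.array([1.0, 0.0, 0.0, 0.0])
        result = convolutive_mix(hs, ls, spec, a_taps=identity, b_taps=identity)
        np.testing.assert_array_equal(result.signal.samples, hs.samples + ls.samples)

    def test_rate_mismatch_rejected(self, rng):
        hs = Signal(rng.standard_normal(100), 8000.0)
        ls = Signal(rng.standard_normal(100), 4000.0)
        spec = MixtureSpec(flow="low", mixture_type="normal-normal", seed=0)
        with pytest.raises(ParameterError):
            convolutive_mix(hs, ls, spec)

    def test_length_mismatch_rejected(self, rng):
        hs = Signal(rng.standard_normal(100), RATE)
        ls = Signal(rng.standard_normal(101), RATE)
        spec = MixtureSpec(flow="low", mixture_type="normal-normal", seed=0)
        with pytest.raises(ParameterError):
            convolutive_mix(hs, ls, spec)

    def test_explicit_a_norm_validated_against_cell(self):
        with pytest.raises(ParameterError):
            MixtureSpec(flow="low", mixture_type="normal-normal", seed=0, a_norm=2.0)


class TestFlowMonotonicity:
    def test_ls_to_hs_power_ratio_increases_with_flow(self):
        ratios = []
        for flow in FLOWS:
            vals = []
            for seed in range(6):
                r = make_mixture("normal-normal", flow, duration_s=6.0, seed=seed)
                mask = np.zeros(r.signal.n, dtype=bool)
                for seg in r.truth.segments:
                    mask[seg.start : seg.end] = True
                hs_power = np.mean(r.signal.samples[mask] ** 2)
                ls_power = np.mean(r.signal.samples[~mask] ** 2)
                vals.append(ls_power / hs_power)
            ratios.append(np.mean(vals))
        assert ratios[0] < ratios[1] < ratios[2]


class TestMakeMixture:
    def test_reproducible(self):
        a = make_mixture("normal-normal", "medium", duration_s=4.0, seed=9)
        b = make_mixture("normal-normal", "medium", duration_s=6.0, seed=9)
        # different durations obviously differ; same call must be identical
        c = make_mixture("normal-normal", "medium", duration_s=4.0, seed=9)
        np.testing.assert_array_equal(a.signal.samples, c.signal.samples)
        assert a.a_norm == c.a_norm
        assert b.signal.n != a.signal.n

    def test_truth_labels_match_components(self):
        r = make_mixture("normal-abnormal", "low", duration_s=4.0, seed=0)
        labels = set(r.truth.labels)
        assert {"S1", "S2"} <= labels
        assert labels & {"S3", "S4"}

    def test_normal_hs_has_no_gallop(self):
        r = make_mixture("normal-normal", "low", duration_s=4.0, seed=0)
        assert set(r.truth.labels) == {"S1", "S2"}

    def test_truth_segments_valid(self):
        r = make_mixture("abnormal-abnormal", "high", duration_s=4.0, seed=1)
        prev_end = 0
        for seg in r.truth.segments:
            assert prev_end <= seg.start < seg.end <= r.signal.n
            prev_end = seg.end

    def test_unknown_type_rejected(self):
        with pytest.raises(ParameterError):
            make_mixture("bogus-normal", "low")


class TestTruthCsv:
    def test_round_trip(self, tmp_path):
        r = make_mixture("normal-normal", "low", duration_s=4.0, seed=0)
        path = tmp_path / "truth.csv"
        write_truth_csv(r.truth, path)
        assert path.read_text().splitlines()[0] == "start_sample,end_sample,label"
        back = read_truth_csv(path, r.signal.n)
        assert len(back.segments) == len(r.truth.segments)
        assert back.labels == r.truth.labels
        for a, b in zip(back.segments, r.truth.segments):
            assert (a.start, a.end) == (b.start, b.end)
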