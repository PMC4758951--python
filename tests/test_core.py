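import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbmkit.core import (
    FeatureKey,
    FeatureModel,
    IntensityModel,
    PositionalBias,
    ProbeTable,
    ddG_over_RT,
    enumerate_views,
    features_of,
    predict_batch,
    predict_intensity,
    relative_affinity,
    revcomp,
)
from util import oracle_predict, random_dna, random_model

dna = st.text(alphabet="ACGT", min_size=1, max_size=20)


@pytest.fixture
def two_col_model():
    # reference AC; pos0 penalties A0 C1 G2 T3, pos1 C0 A0.5 G1.5 T2.5
    mono = np.array([[0.0, 1.0, 2.0, 3.0], [0.5, 0.0, 1.5, 2.5]])
    return FeatureModel("AC", mono)


class TestEnumerateViews:
    def test_full_length_probe_has_one_offset_per_strand(self):
        assert enumerate_views("ACGT", 4) == [
            (0, "+", "ACGT"),
            (0, "-", "ACGT"),
        ]

    def test_windows_and_reverse_complements(self):
        views = enumerate_views("ACGTA", 4)
        assert [v[2] for v in views if v[1] == "+"] == ["ACGT", "CGTA"]
        assert [v[2] for v in views if v[1] == "-"] == ["ACGT", "TACG"]
        assert [v[:2] for v in views] == [(0, "+"), (1, "+"), (0, "-"), (1, "-")]

    def test_view_count(self):
        probe = "A" * 36
        assert len(enumerate_views(probe, 10)) == 2 * (36 - 10 + 1)

    def test_motif_longer_than_probe_raises(self):
        with pytest.raises(ValueError, match="longer than probe"):
            enumerate_views("ACG", 4)

    @settings(derandomize=True, max_examples=50)
    @given(dna, st.integers(min_value=1, max_value=8))
    def test_counts_and_reverse_complement_content(self, probe, L):
        if L > len(probe):
            return
        views = enumerate_views(probe, L)
        k = len(probe) - L + 1
        assert len(views) == 2 * k
        for (of, sf, wf), (orv, srv, wrv) in zip(views[:k], views[k:]):
            assert of == orv and sf == "+" and srv == "-"
            assert wrv == revcomp(wf)


class TestFeatures:
    def test_mono_only(self):
        assert features_of("AC") == {
            FeatureKey("mono", 0, "A"),
            FeatureKey("mono", 1, "C"),
        }

    def test_with_dinucleotides(self):
        assert features_of("AC", include_di=True) == {
            FeatureKey("mono", 0, "A"),
            FeatureKey("mono", 1, "C"),
            FeatureKey("di", 0, "AC"),
        }

    def test_counts_for_octamer(self):
        assert len(features_of("ACGTACGT", include_di=True)) == 8 + 7

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            features_of("ACGU")


class TestFreeEnergy:
    def test_reference_is_zero(self, two_col_model):
        assert ddG_over_RT("AC", two_col_model) == 0.0
        assert relative_affinity("AC", two_col_model) == 1.0

    def test_mono_sum(self, two_col_model):
        assert ddG_over_RT("GC", two_col_model) == pytest.approx(2.0)

    def test_di_adds_on_top(self, two_col_model):
        di = np.zeros((1, 16))
        di[0, 4 * 2 + 0] = 0.7  # pair GA
        m = FeatureModel("AC", two_col_model.mono.copy(), di)
        assert ddG_over_RT("GA", m) == pytest.approx(2.0 + 0.5 + 0.7)

    def test_exponential_map_and_monotonicity(self, two_col_model):
        assert relative_affinity("CC", two_col_model) == pytest.approx(
            math.exp(-1.0)
        )
        vals = [relative_affinity(w, two_col_model) for w in ("AC", "CC", "GC")]
        assert vals[0] > vals[1] > vals[2]

    def test_length_mismatch(self, two_col_model):
        with pytest.raises(ValueError):
            ddG_over_RT("ACG", two_col_model)


class TestPredictIntensity:
    def test_zero_gamma_gives_intercept(self, two_col_model):
        bias = PositionalBias(np.array([0.0, 0.0, 1e-300, 0.0]))
        im = IntensityModel(beta0=7.0, beta1=2.0)
        assert predict_intensity("ACA", two_col_model, bias, im) == pytest.approx(
            7.0
        )

    def test_linear_sum_over_views(self, two_col_model):
        bias = PositionalBias(np.ones(4))
        im = IntensityModel(beta0=0.0, beta1=1.0)
        got = predict_intensity("ACA", two_col_model, bias, im)
        expect = sum(
            math.exp(-ddG_over_RT(w, two_col_model))
            for _, _, w in enumerate_views("ACA", 2)
        )
        assert got == pytest.approx(expect, rel=1e-12)

    def test_saturation_limit(self, two_col_model):
        # one dominant view with huge x contributes ~1 -> y ~ beta0+beta1
        bias = PositionalBias(np.array([1e9, 0, 0, 0]))
        im = IntensityModel(
            beta0=1.0, beta1=2.0, ddG_ns_over_RT=200.0, saturating=True
        )
        assert predict_intensity("ACA", two_col_model, bias, im) == pytest.approx(
            3.0, abs=1e-6
        )

    def test_gamma_shape_mismatch(self, two_col_model):
        with pytest.raises(ValueError):
            predict_intensity(
                "ACA", two_col_model, PositionalBias(np.ones(3)), IntensityModel()
            )

    def test_saturating_output_bounded(self):
        rng = np.random.default_rng(0)
        model = random_model(rng, 5)
        probe = random_dna(rng, 20)
        V = 2 * (20 - 5 + 1)
        bias = PositionalBias(rng.uniform(0, 1, V) + 1e-6)
        im = IntensityModel(
            beta0=3.0, beta1=5.0, ddG_ns_over_RT=1.0, saturating=True
        )
        y = predict_intensity(probe, model, bias, im)
        assert 3.0 <= y <= 3.0 + 5.0 * V


class TestVectorisedEngine:
    def test_view_sum_oracle(self):
        """predict equals an independent brute-force loop over substrings
        and their reverse complements, to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            L = int(rng.integers(2, 7))
            plen = int(rng.integers(L, L + 15))
            model = random_model(rng, L, with_di=bool(rng.integers(0, 2)))
            probe = random_dna(rng, plen)
            gamma = rng.uniform(0, 1, 2 * (plen - L + 1))
            gamma[int(rng.integers(len(gamma)))] = 1.0
            im = IntensityModel(beta0=1.5, beta1=3.0)
            got = predict_intensity(probe, model, PositionalBias(gamma), im)
            want = oracle_predict(probe, model, gamma, 1.5, 3.0)
            assert got == pytest.approx(want, abs=1e-12 * max(1, abs(want)))

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, 6, with_di=True)
        seqs = [random_dna(rng, 25) for _ in range(20)]
        gamma = rng.uniform(0.1, 1, 2 * 20)
        im = IntensityModel(beta0=2.0, beta1=4.0)
        from pbmkit.core import encode_sequences

        batch = predict_batch(encode_sequences(seqs), model, gamma, im)
        for s, b in zip(seqs, batch):
            assert b == pytest.approx(
                predict_intensity(s, model, PositionalBias(gamma), im), rel=1e-12
            )

    def test_strand_symmetry_of_linear_model(self):
        """With gamma mirrored between strands, a probe and its reverse
        complement predict identically for any model."""
        rng = np.random.default_rng(2)
        model = random_model(rng, 5)
        probe = random_dna(rng, 18)
        k = 18 - 5 + 1
        g_off = rng.uniform(0.1, 1, k)
        # reverse view at mirrored offset o corresponds to forward offset
        # len-L-o of the reverse-complemented probe
        gamma = np.concatenate([g_off, g_off[::-1]])
        im = IntensityModel(beta0=0.0, beta1=1.0)
        a = predict_intensity(probe, model, PositionalBias(gamma), im)
        b = predict_intensity(revcomp(probe), model, PositionalBias(gamma), im)
        assert a == pytest.approx(b, rel=1e-12)


class TestProbeTable:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ProbeTable(["a"], ["ACGT"], np.array([np.inf]))
        with pytest.raises(ValueError):
            ProbeTable(["a", "b"], ["ACGT", "ACG"], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ProbeTable(["a"], ["ACGN"], np.array([1.0]))
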