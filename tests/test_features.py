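import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afrisk import features
from afrisk.features import (
    Pattern,
    ectopy_metrics,
    isdefined,
    normalized_delta_rr,
    poincare_descriptors,
    spectral_power,
    time_domain,
)
from afrisk.synth import AFParams, SinusParams, inject_pacs, simulate_af, simulate_sinus
from afrisk.ingest import segment_hours

from conftest import segment_from_rr


def naive_time_domain(rr, labels):
    """Independent brute-force oracle: plain loops over the definitions."""
    nn, pairs = [], []
    for i in range(1, len(rr)):
        if labels[i - 1] == "N" and labels[i] == "N":
            nn.append(rr[i])
            if i + 1 < len(rr) and labels[i + 1] == "N":
                pairs.append(rr[i + 1] - rr[i])
    mean = sum(nn) / len(nn)
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in nn) / len(nn))
    rmssd = math.sqrt(sum(d * d for d in pairs) / len(pairs))
    pnn50 = 100.0 * sum(1 for d in pairs if abs(d) > 50.0) / len(pairs)
    return mean, sdnn, rmssd, pnn50


class TestTimeDomain:
    def test_constant_series(self):
        seg = segment_from_rr([800.0] * 3600)
        td = time_domain(seg)
        assert td.mean_nn == 800.0
        assert td.sdnn == 0.0
        assert td.rmssd == 0.0
        assert td.pnn50 == 0.0
        assert td.cv == 0.0

    def test_alternating_800_860(self):
        seg = segment_from_rr([800.0, 860.0] * 500)
        td = time_domain(seg)
        assert td.rmssd == pytest.approx(60.0, rel=1e-12)
        assert td.pnn50 == 100.0
        assert td.sdnn == pytest.approx(30.0, abs=0.01)

    def test_matches_naive_oracle(self):
        s = simulate_sinus(SinusParams(), 4200, seed=77)
        seg = segment_hours(s)[0]
        td = time_domain(seg)
        mean, sdnn, rmssd, pnn50 = naive_time_domain(list(seg.rr), list(seg.labels))
        assert td.mean_nn == pytest.approx(mean, rel=1e-9)
        assert td.sdnn == pytest.approx(sdnn, rel=1e-9)
        assert td.rmssd == pytest.approx(rmssd, rel=1e-9)
        assert td.pnn50 == pytest.approx(pnn50, rel=1e-9)
        assert td.cv == td.sdnn / td.mean_nn

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_naive_oracle_property(self, seed):
        s = simulate_sinus(SinusParams(noise_sd=30.0), 400, seed=seed)
        s, _ = inject_pacs(s, 40.0, seed=seed + 1)
        seg = segment_hours(s, min_beats=1)[0]
        td = time_domain(seg)
        mean, sdnn, rmssd, pnn50 = naive_time_domain(list(seg.rr), list(seg.labels))
        assert td.mean_nn == pytest.approx(mean, rel=1e-9)
        assert td.sdnn == pytest.approx(sdnn, rel=1e-9)
        assert td.rmssd == pytest.approx(rmssd, rel=1e-9)
        assert td.pnn50 == pytest.approx(pnn50, rel=1e-9)

    def test_too_few_nn_pairs_undefined(self):
        seg = segment_from_rr([800.0, 810.0, 820.0], labels=["A", "A", "A"])
        td = time_domain(seg)
        assert not td.defined
        assert not isdefined(td.mean_nn)


class TestNormalizedDeltaRR:
    def test_equal_pair_is_zero(self):
        seg = segment_from_rr([700.0, 800.0, 800.0])
        assert normalized_delta_rr(seg)[0] == 0.0

    def test_1000_500_gives_one_third(self):
        seg = segment_from_rr([800.0, 1000.0, 500.0])
        assert normalized_delta_rr(seg)[0] == pytest.approx(1.0 / 3.0, rel=1e-15)

    def test_matches_elementwise_oracle_exactly(self):
        s = simulate_sinus(SinusParams(), 1800, seed=3)
        s, _ = inject_pacs(s, 25.0, seed=4)
        seg = segment_hours(s, min_beats=1)[0]
        vals = normalized_delta_rr(seg)
        expected = [
            (seg.rr[i] - seg.rr[i + 1]) / (seg.rr[i] + seg.rr[i + 1])
            for i in range(1, seg.n_beats - 1)
        ]
        assert np.array_equal(vals, np.array(expected))
        assert np.all(np.abs(vals) < 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(min_value=300.0, max_value=2000.0),
        b=st.floats(min_value=300.0, max_value=2000.0),
    )
    def test_antisymmetric(self, a, b):
        fwd = normalized_delta_rr(segment_from_rr([800.0, a, b]))[0]
        rev = normalized_delta_rr(segment_from_rr([800.0, b, a]))[0]
        assert fwd == -rev


class TestPoincare:
    def test_alternating_closed_form(self):
        seg = segment_from_rr([800.0, 860.0] * 500)
        pc = poincare_descriptors(seg)
        assert pc.sd1 == pytest.approx(math.sqrt(1800.0), rel=1e-12)
        assert pc.sd2 == 0.0

    def test_constant_series_degenerate(self):
        seg = segment_from_rr([800.0] * 600)
        pc = poincare_descriptors(seg)
        assert pc.sd1 == 0.0
        assert pc.sd2 == 0.0
        assert pc.dispersion == 0.0
        assert pc.pattern is Pattern.COMET

    def test_iid_limit(self):
        s = simulate_af(AFParams(), 3600, seed=5)
        seg = segment_hours(s, min_beats=1)[0]
        pc = poincare_descriptors(seg)
        sdnn = float(np.std(seg.rr[1:-1]))
        assert pc.sd1 == pytest.approx(sdnn, rel=0.05)
        assert pc.sd2 == pytest.approx(sdnn, rel=0.05)
        assert pc.pattern is Pattern.DISPERSED

    def test_identity_sd1_sd2_sdnn(self):
        for seed in range(5):
            s = simulate_sinus(SinusParams(noise_sd=25.0), 900, seed=seed)
            seg = segment_hours(s, min_beats=1)[0]
            pc = poincare_descriptors(seg)
            td = time_domain(seg)
            assert pc.sd1**2 + pc.sd2**2 == pytest.approx(
                2.0 * td.sdnn**2, rel=1e-6
            )

    def test_rmssd_relation_zero_mean_differences(self):
        seg = segment_from_rr([800.0, 840.0] * 300)
        pc = poincare_descriptors(seg)
        td = time_domain(seg)
        assert pc.sd1 == pytest.approx(td.rmssd / math.sqrt(2.0), rel=1e-9)

    def test_too_few_pairs_undefined(self):
        seg = segment_from_rr([800.0] * 50)
        pc = poincare_descriptors(seg)
        assert not pc.defined
        assert pc.pattern is None


class TestSpectral:
    def test_constant_rr_no_power(self):
        seg = segment_from_rr([800.0] * 3000)
        sp = spectral_power(seg)
        assert sp.lf_power == 0.0
        assert sp.hf_power == 0.0
        assert not isdefined(sp.lf_hf)

    def test_single_hf_tone(self):
        s = simulate_sinus(SinusParams(a_lf=0.0, a_hf=30.0, noise_sd=0.0), 3600, seed=1)
        seg = segment_hours(s)[0]
        sp = spectral_power(seg)
        assert sp.hf_power / (sp.lf_power + sp.hf_power) > 0.9

    def test_single_lf_tone(self):
        s = simulate_sinus(SinusParams(a_lf=30.0, a_hf=0.0, noise_sd=0.0), 3600, seed=1)
        seg = segment_hours(s)[0]
        sp = spectral_power(seg)
        assert sp.lf_power / (sp.lf_power + sp.hf_power) > 0.9

    def test_two_equal_tones(self):
        s = simulate_sinus(SinusParams(a_lf=30.0, a_hf=30.0, noise_sd=0.0), 3600, seed=2)
        seg = segment_hours(s)[0]
        sp = spectral_power(seg)
        assert 0.7 <= sp.lf_hf <= 1.4

    def test_short_span_undefined(self):
        seg = segment_from_rr([800.0, 810.0] * 40)
        assert not spectral_power(seg).defined


class TestEctopy:
    def test_no_pacs(self):
        seg = segment_from_rr([800.0] * 1000)
        em = ectopy_metrics(seg)
        assert em.pac_count == 0
        assert em.pac_per_hour == 0.0
        assert em.max_pac_run == 0

    def test_isolated_pacs(self):
        labels = ["N"] * 4500
        for i in range(100, 4500, 370):
            labels[i] = "A"
        n_a = labels.count("A")
        seg = segment_from_rr([800.0] * 4500, labels=labels)
        em = ectopy_metrics(seg)
        assert em.pac_count == n_a
        assert em.max_pac_run == 1
        assert em.pac_per_hour == pytest.approx(
            n_a / (seg.covered_duration / 3600.0)
        )

    def test_couplet_run(self):
        labels = ["N"] * 500
        labels[100] = labels[101] = "A"
        labels[300] = "A"
        seg = segment_from_rr([800.0] * 500, labels=labels)
        em = ectopy_metrics(seg)
        assert em.pac_count == 3
        assert em.max_pac_run == 2

    def test_generator_couplet(self):
        s = simulate_sinus(SinusParams(), 3600, seed=42)
        injected, _ = inject_pacs(s, 40.0, seed=43)
        seg = segment_hours(injected)[0]
        em = ectopy_metrics(seg)
        assert em.pac_count == int(np.sum(seg.labels == "A"))
        assert em.max_pac_run >= 1
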