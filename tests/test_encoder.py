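"""Spatial/temporal encoding: sign projection, fusion, n-grams, windows."""

import numpy as np
import pandas as pd
import pytest

from hdcfusion import (
    DatasetLayout,
    FeatureSample,
    ModalityConfig,
    NgramWindow,
    bind,
    encode_modality,
    encode_sample,
    permute,
    project_feature,
    provision,
    stream_encode,
    stream_encode_late_fusion,
    temporal_encode,
)
from hdcfusion.encoder import (
    spatial_encode_batch,
    temporal_encode_batch,
)
from hdcfusion.stream import FeatureStream, channel_columns

from conftest import bits

D = 65  # deliberately not a power of two: rule-90 strategies stay healthy


def make_stream(layout, values, labels_v=None, labels_a=None, subject=0, trial=0):
    """Wrap a (S, C) value matrix into a single-trial FeatureStream."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    s = len(values)
    meta = pd.DataFrame(
        {
            "subject": [subject] * s,
            "trial": [trial] * s,
            "sample": range(s),
            "label_valence": labels_v if labels_v is not None else [0] * s,
            "label_arousal": labels_a if labels_a is not None else [0] * s,
        }
    )
    vals = pd.DataFrame(values, columns=channel_columns(values.shape[1]))
    return FeatureStream(layout, pd.concat([meta, vals], axis=1))


@pytest.fixture
def toy_memory(tiny_layout):
    return provision("unoptimized", tiny_layout, D, seed=4)


class TestProjectFeature:
    def test_sign_selects_projection(self, toy_memory):
        cvs = toy_memory.channel_set(0)
        assert np.array_equal(project_feature(0.3, cvs), bind(cvs.iM, cvs.PFP))
        assert np.array_equal(project_feature(-0.3, cvs), bind(cvs.iM, cvs.NFP))
        # zero counts as non-negative
        assert np.array_equal(project_feature(0.0, cvs), bind(cvs.iM, cvs.PFP))

    def test_out_of_range_rejected(self, toy_memory):
        with pytest.raises(ValueError):
            project_feature(1.5, toy_memory.channel_set(0))


class TestEncodeModality:
    def test_single_channel_modality_equals_projection(self):
        layout = DatasetLayout([ModalityConfig("only", 1)])
        mem = provision("unoptimized", layout, D, seed=1)
        sample = FeatureSample(np.array([-0.4]))
        assert np.array_equal(
            encode_modality(sample, layout.modalities[0], mem),
            project_feature(-0.4, mem.channel_set(0)),
        )

    def test_matches_counting_oracle(self, tiny_layout, toy_memory, rng):
        sample = FeatureSample(rng.uniform(-1, 1, tiny_layout.total_channels))
        mod = tiny_layout.modalities[1]  # 5 channels, odd: no ties
        got = encode_modality(sample, mod, toy_memory)
        sl = tiny_layout.channel_slices()[1]
        projections = [
            project_feature(sample.values[i], toy_memory.channel_set(i))
            for i in range(sl.start, sl.stop)
        ]
        counts = np.sum(projections, axis=0)
        assert np.array_equal(got, (counts > len(projections) / 2).astype(np.uint8))

    def test_wrong_channel_count_rejected(self, tiny_layout, toy_memory):
        with pytest.raises(ValueError):
            encode_modality(
                FeatureSample(np.zeros(3)), tiny_layout.modalities[0], toy_memory
            )


class TestEncodeSample:
    def test_single_modality_layout_reduces_to_modality_encoding(self):
        layout = DatasetLayout([ModalityConfig("m", 5)])
        mem = provision("unoptimized", layout, D, seed=2)
        sample = FeatureSample(np.linspace(-1, 1, 5))
        assert np.array_equal(
            encode_sample(sample, layout, mem),
            encode_modality(sample, layout.modalities[0], mem),
        )

    def test_deterministic(self, tiny_layout, toy_memory, rng):
        sample = FeatureSample(rng.uniform(-1, 1, tiny_layout.total_channels))
        a = encode_sample(sample, tiny_layout, toy_memory)
        b = encode_sample(sample, tiny_layout, toy_memory)
        assert np.array_equal(a, b)

    def test_sign_flip_of_one_modality_moves_vector_half_dimension(
        self, tiny_layout, rng
    ):
        mem = provision("unoptimized", tiny_layout, 10_000, seed=6)
        vals = rng.uniform(0.1, 1.0, tiny_layout.total_channels)
        flipped = vals.copy()
        sl = tiny_layout.channel_slices()[2]
        flipped[sl] = -flipped[sl]
        mod = tiny_layout.modalities[2]
        a = encode_modality(FeatureSample(vals), mod, mem)
        b = encode_modality(FeatureSample(flipped), mod, mem)
        assert 0.4 < np.mean(a != b) < 0.6

    def test_independent_sign_patterns_keep_separating_distance(self, tiny_layout, rng):
        # Two samples with independent random signs agree on ~half their
        # channels, so their bundles' per-position counts have correlation
        # ~1/2 and the majority bits agree w.p. 1/2 + arcsin(1/2)/pi = 2/3:
        # the expected normalized distance is 1/3 — well away from both 0
        # (identical) and the ~0 distance of same-class samples at full
        # separability, which is what inference relies on.
        mem = provision("unoptimized", tiny_layout, 10_000, seed=8)
        dists = []
        for _ in range(10):
            a = encode_sample(
                FeatureSample(rng.choice([-0.5, 0.5], tiny_layout.total_channels)),
                tiny_layout, mem,
            )
            b = encode_sample(
                FeatureSample(rng.choice([-0.5, 0.5], tiny_layout.total_channels)),
                tiny_layout, mem,
            )
            dists.append(np.mean(a != b))
        assert 0.2 < min(dists) and max(dists) < 0.47


class TestTemporalEncode:
    def test_unigram_is_spatial_vector(self, tiny_layout, toy_memory, rng):
        s = FeatureSample(rng.uniform(-1, 1, tiny_layout.total_channels))
        assert np.array_equal(
            temporal_encode(NgramWindow([s]), tiny_layout, toy_memory),
            encode_sample(s, tiny_layout, toy_memory),
        )

    def test_bigram_by_hand(self):
        # SE_{j-1}=1010, SE_j=1100: rho(1010)=0101, TE = 1100 ^ 0101 = 1001.
        se = np.stack([bits("1010"), bits("1100")])
        te = temporal_encode_batch(se, 2)
        assert np.array_equal(te[0], bits("1001"))

    def test_window_shift_recursion(self, tiny_layout, toy_memory, rng):
        # TE over N samples = SE_last ^ rho(TE over the earlier N-1 samples).
        samples = [
            FeatureSample(rng.uniform(-1, 1, tiny_layout.total_channels))
            for _ in range(4)
        ]
        full = temporal_encode(NgramWindow(samples), tiny_layout, toy_memory)
        head = temporal_encode(NgramWindow(samples[:-1]), tiny_layout, toy_memory)
        last = encode_sample(samples[-1], tiny_layout, toy_memory)
        assert np.array_equal(full, bind(last, permute(head, +1)))

    def test_repeatable(self, tiny_layout, toy_memory, rng):
        samples = [
            FeatureSample(rng.uniform(-1, 1, tiny_layout.total_channels))
            for _ in range(3)
        ]
        w = NgramWindow(samples)
        assert np.array_equal(
            temporal_encode(w, tiny_layout, toy_memory),
            temporal_encode(w, tiny_layout, toy_memory),
        )


class TestBatchEquivalence:
    def test_batch_spatial_equals_per_sample(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (6, tiny_layout.total_channels))
        batch = spatial_encode_batch(values, toy_memory)
        for j in range(6):
            single = encode_sample(FeatureSample(values[j]), tiny_layout, toy_memory)
            assert np.array_equal(batch[j], single)

    def test_stream_encode_equals_window_composition(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (7, tiny_layout.total_channels))
        stream = make_stream(tiny_layout, values)
        pairs = stream_encode(stream, 3, tiny_layout, toy_memory)
        assert len(pairs) == 5
        for w, (vec, label) in enumerate(pairs):
            window = NgramWindow(
                [FeatureSample(values[j]) for j in range(w, w + 3)]
            )
            assert np.array_equal(
                vec, temporal_encode(window, tiny_layout, toy_memory)
            )
            assert label == 0


class TestStreamEncode:
    def test_window_count_same_label(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (5, tiny_layout.total_channels))
        pairs = stream_encode(make_stream(tiny_layout, values), 3, tiny_layout, toy_memory)
        assert len(pairs) == 3  # 5 - 3 + 1

    def test_transitionary_windows_dropped(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (5, tiny_layout.total_channels))
        stream = make_stream(tiny_layout, values, labels_v=[0, 0, 1, 1, 1])
        pairs = stream_encode(stream, 3, tiny_layout, toy_memory)
        assert len(pairs) == 1 and pairs[0][1] == 1
        kept = stream_encode(
            stream, 3, tiny_layout, toy_memory, exclude_transitionary=False
        )
        assert len(kept) == 3
        assert [l for _, l in kept] == [-1, -1, 1]

    def test_too_short_trial_yields_no_windows(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (2, tiny_layout.total_channels))
        pairs = stream_encode(make_stream(tiny_layout, values), 3, tiny_layout, toy_memory)
        assert pairs == []

    def test_windows_never_cross_trial_boundaries(self, tiny_layout, toy_memory, rng):
        a = make_stream(tiny_layout, rng.uniform(-1, 1, (4, 15)), trial=0)
        b = make_stream(tiny_layout, rng.uniform(-1, 1, (4, 15)), trial=1)
        merged = FeatureStream(
            tiny_layout, pd.concat([a.frame, b.frame], ignore_index=True)
        )
        pairs = stream_encode(merged, 3, tiny_layout, toy_memory)
        assert len(pairs) == 4  # 2 windows per trial, none spanning the join


class TestLateFusion:
    def test_single_modality_matches_early_fusion(self, rng):
        layout = DatasetLayout([ModalityConfig("m", 5)])
        mem = provision("unoptimized", layout, D, seed=3)
        values = rng.uniform(-1, 1, (6, 5))
        stream = make_stream(layout, values)
        early = stream_encode(stream, 3, layout, mem)
        late = stream_encode_late_fusion(stream, 3, layout, mem)
        for (ev, el), (lv, ll) in zip(early, late):
            assert np.array_equal(ev, lv) and el == ll

    def test_matches_per_modality_composition(self, tiny_layout, toy_memory, rng):
        values = rng.uniform(-1, 1, (5, tiny_layout.total_channels))
        stream = make_stream(tiny_layout, values)
        late = stream_encode_late_fusion(stream, 3, tiny_layout, toy_memory)
        # oracle: temporal-encode each modality's SE stream, then bundle
        from hdcfusion.hv_core import bundle

        per_mod_te = []
        for mod, sl in zip(tiny_layout.modalities, tiny_layout.channel_slices()):
            ses = []
            for j in range(5):
                projections = [
                    project_feature(values[j, i], toy_memory.channel_set(i))
                    for i in range(sl.start, sl.stop)
                ]
                ses.append(bundle(projections))
            per_mod_te.append(temporal_encode_batch(np.stack(ses), 3))
        for w, (vec, _) in enumerate(late):
            expected = bundle([te[w] for te in per_mod_te])
            assert np.array_equal(vec, expected)
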