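"""Attention operators vs brute-force oracles, partition roundtrips, and
the structural invariants of the local/global/frame decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cinedenoise.attention as at
from cinedenoise.attention import (
    AttentionGeometry,
    ConfigurationError,
    GeometryError,
    ImageSeries5D,
    QKVProjection,
    RelPosBias,
)
from cinedenoise.reference import (
    conv2d_bruteforce,
    frame_attention_bruteforce,
    scaled_dot_bruteforce,
)


class TestImageSeries5D:
    def test_rejects_wrong_rank_and_nonfinite(self):
        with pytest.raises(ValueError):
            ImageSeries5D(np.zeros((2, 3, 4, 5)))
        with pytest.raises(ValueError):
            ImageSeries5D(np.full((1, 1, 1, 2, 2), np.nan))

    def test_complex_real_channel_pairing(self, rng):
        z = rng.normal(size=(1, 2, 3, 4, 4)) + 1j * rng.normal(size=(1, 2, 3, 4, 4))
        s = ImageSeries5D(z)
        assert s.is_complex
        r = s.as_real_channels()
        assert r.shape == (1, 4, 3, 4, 4)
        assert np.array_equal(r.values[:, 0], z.real[:, 0])
        assert np.array_equal(r.values[:, 1], z.imag[:, 0])


class TestGeometry:
    def test_patch_count(self):
        geom = AttentionGeometry(window_px=4, patch_px=2)
        assert geom.patches_per_window == 4
        assert AttentionGeometry(8, 8).patches_per_window == 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            AttentionGeometry(window_px=6, patch_px=4)
        with pytest.raises(ConfigurationError):
            AttentionGeometry(4, 2, heads=3).token_length(2)  # 8 % 3 != 0


class TestProjectQKV:
    def test_zero_input_zero_kernels(self):
        proj = QKVProjection(2, np.random.default_rng(0))
        for p in (proj.wq, proj.wk, proj.wv):
            p.data[...] = 0
        q, k, v = at.project_qkv(np.zeros((1, 2, 2, 4, 4)), proj)
        assert not q.any() and not k.any() and not v.any()

    def test_identity_kernel(self, rng):
        proj = QKVProjection(3, np.random.default_rng(0))
        proj.wq.data[...] = 0
        for c in range(3):
            proj.wq.data[c, c, 1, 1] = 1.0
        proj.bq.data[...] = 0
        x = rng.normal(size=(1, 3, 2, 5, 5)).astype(np.float32)
        q, _, _ = at.project_qkv(x, proj)
        assert np.abs(q - x).max() < 1e-6

    def test_matches_direct_convolution(self, rng):
        proj = QKVProjection(2, np.random.default_rng(3))
        x = rng.normal(size=(1, 2, 3, 6, 5))
        q, k, v = at.project_qkv(x, proj)
        for out, w, b in [(q, proj.wq, proj.bq.data), (k, proj.wk, None),
                          (v, proj.wv, proj.bv.data)]:
            for f in range(3):
                ref = conv2d_bruteforce(x[:, :, f], w.data, b)
                assert np.abs(out[:, :, f] - ref).max() < 1e-5

    def test_channel_mismatch_raises(self):
        proj = QKVProjection(2, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            at.project_qkv(np.zeros((1, 3, 1, 4, 4)), proj)


class TestPartition:
    def test_degenerate_single_token(self, rng):
        x = rng.normal(size=(1, 3, 1, 4, 4))
        tok, info = at.partition_windows(x, AttentionGeometry(4, 4))
        assert tok.shape == (1, 1, 1, 1, 3 * 16)

    def test_four_patches_per_window(self, rng):
        x = rng.normal(size=(1, 1, 1, 8, 8))
        tok, _ = at.partition_windows(x, AttentionGeometry(4, 2))
        assert tok.shape[3] == 4  # P = (w/p)^2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        h=st.integers(3, 17), w=st.integers(3, 17),
        c=st.integers(1, 3), f=st.integers(1, 3),
        geom=st.sampled_from([(4, 2), (4, 1), (8, 4), (8, 2), (2, 1)]),
    )
    def test_roundtrip_identity_with_padding(self, h, w, c, f, geom):
        x = np.random.default_rng(h * 100 + w).normal(size=(1, c, f, h, w))
        g = AttentionGeometry(*geom)
        tok, info = at.partition_windows(x, g)
        assert tok.shape[-1] == c * g.patch_px**2
        back = at.inverse_partition(tok, info)
        assert np.array_equal(back, x)


class TestScaledDot:
    def test_single_token_passthrough(self, rng):
        dv = rng.normal(size=(1, 4))
        out, a = at.scaled_dot_attention(rng.normal(size=(1, 4)),
                                         rng.normal(size=(1, 4)), dv,
                                         return_weights=True)
        assert np.allclose(a, [[1.0]])
        assert np.allclose(out, dv)

    def test_constant_value_rows(self, rng):
        c = rng.normal(size=4)
        dv = np.tile(c, (5, 1))
        out = at.scaled_dot_attention(rng.normal(size=(5, 3)),
                                      rng.normal(size=(5, 3)), dv)
        assert np.abs(out - c).max() < 1e-12

    def test_matches_two_loop_oracle(self, rng):
        dq, dk, dv = rng.normal(size=(3, 5, 4))
        bias = rng.normal(size=(5, 5))
        out = at.scaled_dot_attention(dq, dk, dv, bias=bias)
        ref = scaled_dot_bruteforce(dq, dk, dv, bias=bias)
        assert np.abs(out - ref).max() < 1e-6


class TestHeads:
    def test_identity_and_extreme_split(self, rng):
        d = rng.normal(size=(3, 4))
        assert np.array_equal(at.split_heads(d, 1)[0], d)
        parts = at.split_heads(d, 4)
        assert all(p.shape == (3, 1) for p in parts)

    def test_contiguous_groups_and_roundtrip(self, rng):
        d = rng.normal(size=(3, 4))
        parts = at.split_heads(d, 2)
        assert np.array_equal(parts[0], d[:, :2])
        assert np.array_equal(parts[1], d[:, 2:])
        assert np.array_equal(at.merge_heads(parts), d)

    def test_indivisible_raises(self, rng):
        with pytest.raises(ConfigurationError):
            at.split_heads(rng.normal(size=(3, 4)), 3)


class TestOperators:
    def test_local_single_patch_window_is_value(self, small_series, rng):
        q, k, v = (rng.normal(size=small_series.shape) for _ in range(3))
        out = at.local_attention(q, k, v, AttentionGeometry(2, 2, 1))
        assert np.abs(out - v).max() < 1e-12

    def test_local_full_frame_equals_oracle(self, rng):
        q, k, v = rng.normal(size=(3, 1, 4, 2, 8, 8))
        out = at.local_attention(q, k, v, AttentionGeometry(8, 1, 1))
        ref = at.full_spatial_attention_oracle(q, k, v)
        assert np.abs(out - ref).max() <= 1e-5

    def test_global_single_window_is_value(self, rng):
        q, k, v = rng.normal(size=(3, 1, 2, 2, 4, 4))
        out = at.global_attention(q, k, v, AttentionGeometry(4, 2, 1))
        assert np.abs(out - v).max() < 1e-12

    def test_global_pixel_windows_equal_oracle(self, rng):
        q, k, v = rng.normal(size=(3, 1, 4, 2, 8, 8))
        out = at.global_attention(q, k, v, AttentionGeometry(1, 1, 1))
        ref = at.full_spatial_attention_oracle(q, k, v)
        assert np.abs(out - ref).max() <= 1e-5

    def test_frame_matches_bruteforce(self, rng):
        q, k, v = rng.normal(size=(3, 1, 4, 4, 3, 3))
        out = at.frame_attention(q, k, v, heads=2)
        ref = frame_attention_bruteforce(q, k, v, heads=2)
        assert np.abs(out - ref).max() < 1e-6

    def test_frame_permutation_equivariance(self, rng):
        q, k, v = rng.normal(size=(3, 1, 2, 5, 4, 4))
        perm = np.array([3, 0, 4, 1, 2])
        out_perm = at.frame_attention(q[:, :, perm], k[:, :, perm],
                                      v[:, :, perm])
        out = at.frame_attention(q, k, v)
        assert np.abs(out_perm - out[:, :, perm]).max() < 1e-10

    def test_shape_preserved_with_padding(self, rng):
        q, k, v = rng.normal(size=(3, 2, 4, 3, 10, 7))
        geom = AttentionGeometry(4, 2, 2)
        for op in (lambda: at.local_attention(q, k, v, geom),
                   lambda: at.global_attention(q, k, v, geom)):
            assert op().shape == (2, 4, 3, 10, 7)

    def test_relative_bias_shifts_logits(self, rng):
        geom = AttentionGeometry(4, 2, 1)
        bias = RelPosBias(geom)
        q, k, v = rng.normal(size=(3, 1, 2, 1, 4, 4))
        base = at.local_attention(q, k, v, geom, bias=bias)
        bias.table.data[...] = rng.normal(size=bias.table.shape)
        shifted = at.local_attention(q, k, v, geom, bias=bias)
        assert np.abs(base - shifted).max() > 1e-6
        # every ordered patch pair has a defined offset; zero offset on the
        # diagonal maps to a single shared table entry
        assert bias.index.shape == (4, 4)
        assert len(set(np.diag(bias.index))) == 1
        assert bias.index.max() < bias.table.shape[-1]


class TestComplexityAccounting:
    def test_counts_match_closed_form_and_scale_linearly(self, rng):
        geom = AttentionGeometry(4, 2, 1)
        for h, w in [(8, 8), (8, 16), (16, 16)]:
            q, k, v = rng.normal(size=(3, 1, 1, 1, h, w))
            with at.LOGIT_COUNTER as counter:
                at.local_attention(q, k, v, geom)
                local = counter.count
            with at.LOGIT_COUNTER as counter:
                at.global_attention(q, k, v, geom)
                glob = counter.count
            expect = at.attention_logit_count(geom, h, w)
            assert local == expect["local"]
            assert glob == expect["global"]
        # doubling H*W doubles the local logit count (linear scaling)
        a = at.attention_logit_count(geom, 8, 8)
        b = at.attention_logit_count(geom, 8, 16)
        assert b["local"] / a["local"] == 2.0
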