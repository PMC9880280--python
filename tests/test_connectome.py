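"""Connectome module: parsing, normalization, delays, null model, synthesis."""

import zipfile

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import skew

from adexbrain import (Connectome, compute_delays, generate_synthetic,
                       load_connectome, normalize_weights, shuffle_weights)


@pytest.fixture()
def trivial_conn():
    return Connectome(weights=np.eye(2), tract_lengths=np.zeros((2, 2)),
                      centres=np.zeros((2, 3)))


class TestConnectomeType:
    def test_trivial_two_region_connectome_is_valid(self, trivial_conn):
        assert trivial_conn.n_regions == 2

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            Connectome(weights=-np.eye(2), tract_lengths=np.zeros((2, 2)),
                       centres=np.zeros((2, 3)))

    def test_asymmetric_tract_lengths_rejected(self):
        tl = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            Connectome(weights=np.eye(2), tract_lengths=tl,
                       centres=np.zeros((2, 3)))

    def test_region_lookup_by_label_and_index(self):
        conn = generate_synthetic(8, seed=0)
        k = conn.region_index("rh-premotor")
        assert conn.labels[k] == "rh-premotor"
        assert conn.region_index(3) == 3
        with pytest.raises(KeyError):
            conn.region_index("no-such-region")


class TestLoaders:
    def test_csv_roundtrip(self, tmp_path):
        conn = generate_synthetic(8, seed=1)
        conn.to_csv_dir(tmp_path / "conn")
        back = load_connectome(tmp_path / "conn", dialect="csv")
        assert back.n_regions == 8
        assert np.allclose(back.weights, conn.weights)
        assert np.allclose(back.tract_lengths, conn.tract_lengths)

    def test_tvb_zip_dialect(self, tmp_path):
        conn = generate_synthetic(68, seed=2)
        zpath = tmp_path / "conn.zip"
        with zipfile.ZipFile(zpath, "w") as zf:
            zf.writestr("weights.txt", "\n".join(
                " ".join(f"{x:.6f}" for x in row) for row in conn.weights))
            zf.writestr("tract_lengths.txt", "\n".join(
                " ".join(f"{x:.6f}" for x in row) for row in conn.tract_lengths))
            zf.writestr("centres.txt", "\n".join(
                f"{lab} {x:.3f} {y:.3f} {z:.3f}"
                for lab, (x, y, z) in zip(conn.labels, conn.centres)))
        back = load_connectome(zpath)
        assert back.n_regions == 68
        assert back.labels[:2] == conn.labels[:2]
        assert np.allclose(back.weights, conn.weights, atol=1e-6)

    def test_ragged_matrix_error_names_offending_line(self, tmp_path):
        d = tmp_path / "conn"
        d.mkdir()
        (d / "weights.csv").write_text("1,0\n0\n")
        (d / "tract_lengths.csv").write_text("0,0\n0,0\n")
        (d / "centres.csv").write_text("0,0,0\n1,1,1\n")
        with pytest.raises(ValueError, match="line 2"):
            load_connectome(d, dialect="csv")


class TestNormalizeWeights:
    def test_hand_arithmetic_before_rescale(self):
        """f = 100, vol_j = vol_k = 10 -> 5 before rescale; with a single
        off-diagonal pair the rescale maps it to 1."""
        f = np.array([[0.0, 100.0], [100.0, 0.0]])
        w = normalize_weights(f, np.array([10.0, 10.0]))
        assert w[0, 1] == pytest.approx(1.0)     # 5.0 rescaled by max
        f2 = np.array([[0.0, 100.0], [40.0, 0.0]])
        w2 = normalize_weights(f2, np.array([10.0, 10.0]))
        assert w2[1, 0] == pytest.approx(40.0 / 100.0)

    def test_uniform_input_gives_uniform_unit_weights(self):
        f = np.ones((4, 4))
        w = normalize_weights(f, np.ones(4))
        assert np.allclose(w, 1.0)

    def test_all_zero_fibers_skip_rescale(self):
        w = normalize_weights(np.zeros((3, 3)), np.ones(3))
        assert np.all(w == 0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights(np.ones((2, 2)), np.array([1.0, 0.0]))


class TestDelays:
    def test_hand_arithmetic(self, trivial_conn):
        conn = generate_synthetic(8, seed=0)
        conn.tract_lengths[0, 1] = conn.tract_lengths[1, 0] = 130.0
        d = compute_delays(conn, v_c=3.0)
        assert d[0, 1] == pytest.approx(130.0 / 3.0)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)

    def test_doubling_speed_halves_delays(self):
        conn = generate_synthetic(8, seed=0)
        d1, d2 = compute_delays(conn, 3.0), compute_delays(conn, 6.0)
        assert np.allclose(d1, 2 * d2)

    def test_nonpositive_speed_rejected(self, trivial_conn):
        with pytest.raises(ValueError):
            compute_delays(trivial_conn, 0.0)


class TestShuffle:
    def test_golden_seeded_permutation(self):
        conn = Connectome(weights=np.array([[0., 1., 2.], [3., 0., 4.],
                                            [5., 6., 0.]]),
                          tract_lengths=np.zeros((3, 3)),
                          centres=np.zeros((3, 3)))
        sh = shuffle_weights(conn, seed=0)
        assert np.array_equal(sh.weights,
                              np.array([[0., 1., 2.], [4., 0., 3.],
                                        [5., 6., 0.]]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_per_row_multisets_and_lengths_preserved(self, seed):
        conn = generate_synthetic(12, seed=3)
        sh = shuffle_weights(conn, seed=seed)
        n = conn.n_regions
        for j in range(n):
            off = [k for k in range(n) if k != j]
            assert sorted(conn.weights[j, off]) == pytest.approx(
                sorted(sh.weights[j, off]))
            assert sh.weights[j, j] == conn.weights[j, j]
        assert sh.weights.sum() == pytest.approx(conn.weights.sum())
        assert np.array_equal(sh.tract_lengths, conn.tract_lengths)


class TestSynthetic:
    def test_weight_distribution_is_heavy_tailed(self, conn68):
        w = conn68.weights[np.triu_indices(68, 1)]
        assert skew(w[w > 0]) > 1.0

    def test_mirrored_centres(self, conn68):
        half = 34
        assert np.allclose(conn68.centres[:half, 0],
                           -conn68.centres[half:, 0])
        assert np.allclose(conn68.centres[:half, 1:],
                           conn68.centres[half:, 1:])

    def test_same_seed_identical(self):
        a = generate_synthetic(16, seed=4)
        b = generate_synthetic(16, seed=4)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.tract_lengths, b.tract_lengths)
        assert np.array_equal(a.centres, b.centres)

    def test_odd_or_tiny_region_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(7)
        with pytest.raises(ValueError):
            generate_synthetic(2)

    def test_hemisphere_tags(self, conn68):
        assert np.all(conn68.hemisphere[:34] == 0)
        assert np.all(conn68.hemisphere[34:] == 1)
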