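"""Core SC matrix model, I/O and transforms."""

import numpy as np
import pytest

from connectotype import (
    ConnectomeMatrix,
    DegenerateInputError,
    Parcellation,
    identity_parcellation,
    normalize_for_km,
    read_sc_matrix,
    reparcellate,
    scale_to_target_mean,
    vectorize_edges,
    write_sc_matrix,
)
from conftest import random_connectome


def _write(tmp_path, M, name="m.tsv"):
    p = tmp_path / name
    np.savetxt(p, np.asarray(M, dtype=float), delimiter="\t")
    return p


class TestReadScMatrix:
    def test_all_zero_matrix_roundtrips(self, tmp_path):
        parc = identity_parcellation(3)
        cm = read_sc_matrix(_write(tmp_path, np.zeros((3, 3))), parc, "s0")
        assert np.all(cm.W == 0)

    def test_diagonal_forced_to_zero_offdiag_preserved(self, tmp_path):
        M = np.full((3, 3), 7.0)
        M[1, 2] = M[2, 1] = 5.0
        cm = read_sc_matrix(_write(tmp_path, M), identity_parcellation(3), "s")
        assert np.all(np.diag(cm.W) == 0)
        assert cm.W[1, 2] == 5.0 and cm.W[0, 1] == 7.0

    def test_asymmetry_beyond_tolerance_rejected(self, tmp_path):
        M = np.zeros((3, 3))
        M[1, 2], M[2, 1] = 5.0, 4.0
        with pytest.raises(ValueError, match="asymmetric"):
            read_sc_matrix(_write(tmp_path, M), identity_parcellation(3), "s")

    def test_negative_entries_rejected(self, tmp_path):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            read_sc_matrix(_write(tmp_path, M), identity_parcellation(3), "s")

    def test_non_square_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("1\t2\t3\n4\t5\t6\n")
        with pytest.raises(ValueError, match="square"):
            read_sc_matrix(p, identity_parcellation(3), "s")

    def test_write_read_roundtrip(self, tmp_path, rng):
        cm = random_connectome(6, rng)
        p = tmp_path / "w.tsv"
        write_sc_matrix(cm, p)
        back = read_sc_matrix(p, cm.parcellation, cm.subject_id)
        np.testing.assert_allclose(back.W, cm.W, rtol=1e-9)


class TestScaleToTargetMean:
    def test_linear_rescale_example(self):
        parc = identity_parcellation(3)
        W = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        out = scale_to_target_mean(ConnectomeMatrix("s", parc, W), 1e-4)
        np.testing.assert_allclose(
            out.W[np.triu_indices(3, 1)], [0.5e-4, 1.0e-4, 1.5e-4]
        )

    def test_fixed_point(self, rng):
        cm = random_connectome(5, rng)
        target = float(cm.W[np.triu_indices(5, 1)].mean())
        out = scale_to_target_mean(cm, target)
        np.testing.assert_allclose(out.W, cm.W, atol=1e-15)

    @pytest.mark.parametrize("target", [1e-4, 0.5, 3.0])
    def test_mean_hits_target(self, rng, target):
        cm = random_connectome(10, rng, density=0.6)
        out = scale_to_target_mean(cm, target)
        assert out.W[np.triu_indices(10, 1)].mean() == pytest.approx(target)
        # zero structure preserved
        assert np.array_equal(out.W == 0, cm.W == 0)

    def test_all_zero_degenerate(self):
        cm = ConnectomeMatrix("z", identity_parcellation(3), np.zeros((3, 3)))
        with pytest.raises(DegenerateInputError):
            scale_to_target_mean(cm, 1.0)


class TestReparcellate:
    def test_hand_computed_block_means(self, two_system_parc):
        # nodes {0,1}->S, {2,3}->T; w01=2, w23=4, w02=1, w03=3, w12=5, w13=7
        W = np.zeros((4, 4))
        W[0, 1], W[2, 3] = 2, 4
        W[0, 2], W[0, 3], W[1, 2], W[1, 3] = 1, 3, 5, 7
        W = W + W.T
        cm = ConnectomeMatrix("s", two_system_parc, W)
        coarse = Parcellation("c", ("S", "T"))
        out = reparcellate(cm, coarse)
        assert out.W[0, 0] == 2 and out.W[1, 1] == 4
        assert out.W[0, 1] == out.W[1, 0] == np.mean([1, 3, 5, 7])

    def test_constant_matrix_gives_constant_coarse(self, two_system_parc):
        W = np.full((4, 4), 3.0)
        np.fill_diagonal(W, 0)
        cm = ConnectomeMatrix("s", two_system_parc, W)
        out = reparcellate(cm, Parcellation("c", ("S", "T")))
        assert np.all(out.W == 3.0)

    def test_identity_mapping_is_noop(self, rng):
        cm = random_connectome(5, rng)
        out = reparcellate(cm, cm.parcellation)
        np.testing.assert_array_equal(out.W, cm.W)

    def test_commutes_with_uniform_scaling(self, rng, two_system_parc):
        cm = random_connectome(4, rng, parc=two_system_parc)
        coarse = Parcellation("c", ("S", "T"))
        a = reparcellate(cm.with_weights(2.5 * cm.W), coarse).W
        b = 2.5 * reparcellate(cm, coarse).W
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_single_node_system_within_entry_zero(self):
        parc = Parcellation("p", ("S", "S", "T"))
        W = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        out = reparcellate(
            ConnectomeMatrix("s", parc, W), Parcellation("c", ("S", "T"))
        )
        assert out.W[1, 1] == 0.0  # T has a single node


class TestVectorizeEdges:
    def test_whole_network_lengths(self):
        from connectotype.parcellation import default_fine_parcellation

        cm = random_connectome(
            100, np.random.default_rng(0), parc=default_fine_parcellation()
        )
        assert len(vectorize_edges(cm)) == 4950

    def test_coarse_whole_length_21(self, rng):
        from connectotype.parcellation import coarse_parcellation

        cm = random_connectome(7, rng, parc=coarse_parcellation())
        assert len(vectorize_edges(cm)) == 21

    @pytest.mark.parametrize("n", [3, 10, 37])
    def test_whole_length_formula(self, rng, n):
        cm = random_connectome(n, rng)
        assert len(vectorize_edges(cm)) == n * (n - 1) // 2

    def test_within_and_between_subsets(self, rng):
        parc = Parcellation("p", ("A", "A", "A", "B", "B"))
        cm = random_connectome(5, rng, parc=parc)
        within = vectorize_edges(cm, "within:A")
        assert len(within) == 3  # 3 choose 2
        np.testing.assert_array_equal(
            within.values, [cm.W[0, 1], cm.W[0, 2], cm.W[1, 2]]
        )
        between = vectorize_edges(cm, "between:A/B")
        assert len(between) == 6
        np.testing.assert_array_equal(
            between.values, cm.W[np.ix_([0, 1, 2], [3, 4])].ravel()
        )

    def test_unknown_system_rejected(self, rng):
        cm = random_connectome(4, rng)
        with pytest.raises(KeyError):
            vectorize_edges(cm, "within:Nope")


class TestNormalizeForKm:
    def test_uniform_weights_become_one(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 0)
        cm = ConnectomeMatrix("s", identity_parcellation(4), W)
        np.testing.assert_allclose(
            normalize_for_km(cm), (W > 0).astype(float)
        )

    def test_zeros_included_in_mean(self):
        # unique weights {0, 2, 4}: mean over all off-diag elements = 2
        W = np.array([[0, 0, 2], [0, 0, 4], [2, 4, 0]], dtype=float)
        cm = ConnectomeMatrix("s", identity_parcellation(3), W)
        C = normalize_for_km(cm)
        assert C[0, 2] == 1.0 and C[1, 2] == 2.0 and C[0, 1] == 0.0

    def test_idempotent_and_scale_invariant(self, rng):
        cm = random_connectome(6, rng)
        C = normalize_for_km(cm)
        C2 = normalize_for_km(cm.with_weights(C))
        np.testing.assert_allclose(C, C2, atol=1e-12)
        C3 = normalize_for_km(cm.with_weights(7.3 * cm.W))
        np.testing.assert_allclose(C, C3, atol=1e-12)

    def test_all_zero_degenerate(self):
        cm = ConnectomeMatrix("z", identity_parcellation(3), np.zeros((3, 3)))
        with pytest.raises(DegenerateInputError):
            normalize_for_km(cm)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=3, max_value=12),
        scale=st.floats(min_value=1e-6, max_value=1e6),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_normalization_scale_invariance_property(n, scale, seed):
        """normalize_for_km(c*W) == normalize_for_km(W) for any c > 0 and
        any nonzero symmetric nonnegative W."""
        rng = np.random.default_rng(seed)
        cm = random_connectome(n, rng)
        if cm.W.max() == 0:
            return
        a = normalize_for_km(cm)
        b = normalize_for_km(cm.with_weights(scale * cm.W))
        np.testing.assert_allclose(a, b, atol=1e-9, rtol=1e-9)

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_transforms_preserve_symmetry_and_nonnegativity(rng):
    parc = Parcellation("p", ("A",) * 3 + ("B",) * 4)
    for _ in range(10):
        cm = random_connectome(7, rng, parc=parc, density=0.7)
        for out in (
            scale_to_target_mean(cm, 0.5).W,
            reparcellate(cm, Parcellation("c", ("A", "B"))).W,
            normalize_for_km(cm),
        ):
            assert np.allclose(out, out.T)
            assert np.all(out >= 0)
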