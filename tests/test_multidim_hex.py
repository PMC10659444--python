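import math

import numpy as np
import pytest

from residuehd import (
    MultiDimBase,
    bind_add,
    bind_mult,
    codebook_cost,
    encode_hex,
    encode_nd,
    enumerate_hex_states,
    hex_entropy,
    hex_project,
    hex_state_count,
    kernel,
    make_anti_base,
    make_hex_base,
    make_residue_base,
    square_entropy,
    square_state_count,
)
from residuehd.multidim_hex import HEX_FRAME, hex_unproject


@pytest.fixture(scope="module")
def mdb2():
    rb1 = make_residue_base([3, 5], 256, nonzero_only=True, seed=21)
    rb2 = make_residue_base([3, 5], 256, nonzero_only=True, seed=22)
    return MultiDimBase((rb1, rb2))


class TestCartesian:
    def test_origin_is_all_ones(self, mdb2):
        z = encode_nd(mdb2, [0, 0])
        assert np.array_equal(z.values, np.ones(mdb2.dim, dtype=complex))

    def test_translation_law_bit_exact(self, mdb2):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = [int(v) for v in rng.integers(-20, 20, size=2)]
            b = [int(v) for v in rng.integers(-20, 20, size=2)]
            lhs = bind_add(encode_nd(mdb2, a), encode_nd(mdb2, b))
            rhs = encode_nd(mdb2, [a[0] + b[0], a[1] + b[1]])
            assert lhs.exact_equals(rhs)

    def test_length_mismatch_rejected(self, mdb2):
        with pytest.raises(ValueError):
            encode_nd(mdb2, [1, 2, 3])

    def test_componentwise_multiplication_law(self, mdb2):
        # multiplicative binding applied per dimension encodes the
        # componentwise product of the two points
        antis = [[make_anti_base(b) for b in rb.bases] for rb in mdb2.bases]
        x, y = [2, 7], [4, 3]
        per_dim = [
            bind_mult(
                rb.encode_factors(xi), rb.encode_factors(yi), rb, anti
            )
            for rb, anti, xi, yi in zip(mdb2.bases, antis, x, y)
        ]
        lhs = bind_add(per_dim[0], per_dim[1])
        rhs = encode_nd(mdb2, [(x[0] * y[0]) % 15, (x[1] * y[1]) % 15])
        assert lhs.exact_equals(rhs)

    def test_product_kernel_law(self):
        # kernel of the 2-D code factorizes over dimensions
        rb1 = make_residue_base([3, 5], 8192, seed=31)
        rb2 = make_residue_base([3, 5], 8192, seed=32)
        mdb = MultiDimBase((rb1, rb2))
        z0 = encode_nd(mdb, [0, 0])
        for dx in ([1, 0], [0, 2], [1, 2], [4, 7]):
            k2d = float(kernel(encode_nd(mdb, dx), z0))
            k1 = float(kernel(rb1.encode(dx[0]), rb1.encode(0)))
            k2 = float(kernel(rb2.encode(dx[1]), rb2.encode(0)))
            assert k2d == pytest.approx(k1 * k2, abs=5 / math.sqrt(8192))


class TestHexFrame:
    def test_rows_unit_norm_and_equiangular(self):
        norms = np.linalg.norm(HEX_FRAME, axis=1)
        assert np.allclose(norms, 1.0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert HEX_FRAME[i] @ HEX_FRAME[j] == pytest.approx(-0.5)

    def test_origin_projects_to_zero(self):
        assert np.allclose(hex_project([0.0, 0.0]), 0.0)

    def test_projection_components_sum_to_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            y = hex_project(rng.normal(size=2))
            assert abs(y.sum()) < 1e-12

    def test_unproject_inverts_project(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=2)
            assert np.allclose(hex_unproject(hex_project(x)), x)


@pytest.fixture(scope="module")
def hb5():
    return make_hex_base(5, 512, seed=41)


class TestHexEncoding:
    def test_zero_sum_constraint(self, hb5):
        assert ((hb5.k1 + hb5.k2 + hb5.k3) % 5 == 0).all()

    def test_all_ones_translation_invisible(self, hb5):
        assert encode_hex(hb5, [1, 1, 1]).exact_equals(encode_hex(hb5, [0, 0, 0]))
        assert encode_hex(hb5, [3, 2, 0]).exact_equals(encode_hex(hb5, [4, 3, 1]))

    def test_path_independence(self, hb5):
        lhs = bind_add(encode_hex(hb5, [1, 0, 0]), encode_hex(hb5, [0, 2, 1]))
        assert lhs.exact_equals(encode_hex(hb5, [1, 2, 1]))

    def test_composed_code_has_period_15(self):
        # moduli {3,5} composed hexagonally: walking one lattice
        # direction returns to the origin encoding only after 3*5 steps
        h3 = make_hex_base(3, 256, seed=42)
        h5 = make_hex_base(5, 256, seed=43)
        z0 = bind_add(encode_hex(h3, [0, 0, 0]), encode_hex(h5, [0, 0, 0]))
        periods = []
        for t in range(1, 16):
            zt = bind_add(encode_hex(h3, [t, 0, 0]), encode_hex(h5, [t, 0, 0]))
            if float(kernel(zt, z0)) > 1 - 1e-6:
                periods.append(t)
        assert periods == [15]
        z15 = bind_add(encode_hex(h3, [15, 0, 0]), encode_hex(h5, [15, 0, 0]))
        assert z15.exact_equals(z0)

    def test_kernel_six_fold_symmetry(self):
        # rotating the offset field by 60 degrees leaves the sampled
        # kernel statistically unchanged
        hb = make_hex_base(3, 8192, seed=44)
        rot = np.array(
            [
                [math.cos(math.pi / 3), -math.sin(math.pi / 3)],
                [math.sin(math.pi / 3), math.cos(math.pi / 3)],
            ]
        )
        rng = np.random.default_rng(45)
        z0 = encode_hex(hb, np.zeros(2))
        diffs = []
        for _ in range(40):
            x = rng.uniform(-1.5, 1.5, size=2)
            k1 = float(kernel(encode_hex(hb, x), z0))
            k2 = float(kernel(encode_hex(hb, rot @ x), z0))
            diffs.append(abs(k1 - k2))
        assert np.mean(diffs) < 0.05


class TestStateCounts:
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5])
    def test_formula_matches_enumeration(self, m):
        assert hex_state_count(m) == 3 * m * m - 3 * m + 1
        assert len(enumerate_hex_states(m)) == hex_state_count(m)

    def test_worked_counts_m5(self):
        assert hex_state_count(5) == 61
        assert square_state_count(5) == 25
        assert codebook_cost(5, "hex") == 15
        assert codebook_cost(5, "square") == 10

    def test_degenerate_single_state(self):
        assert hex_state_count(1) == 1


class TestEntropy:
    def test_hex_exceeds_square_at_equal_modulus(self):
        h = hex_entropy(5, n_samples=20000, seed=0)
        s = square_entropy(5, n_samples=20000, seed=0)
        assert h > s

    def test_single_state_entropy_is_zero(self):
        assert hex_entropy(1, n_samples=500, seed=1) == 0.0

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_entropy_bounded_by_log_state_count(self, m):
        assert hex_entropy(m, n_samples=5000, seed=2) <= math.log2(
            hex_state_count(m)
        )
        assert square_entropy(m, n_samples=5000, seed=2) <= math.log2(
            square_state_count(m)
        )
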