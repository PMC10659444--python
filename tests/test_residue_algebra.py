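import numpy as np
import pytest

from residuehd import (
    Codebook,
    additive_inverse,
    bind_add,
    bind_mult,
    codebook_decode,
    crt_reconstruct,
    encode_residue,
    make_anti_base,
    make_modulus_base,
    make_residue_base,
    multiply_composed,
    residues_of,
)
from residuehd.phasor_core import ModulusBase, PhasorVector


class TestResidueBase:
    def test_effective_range_and_budget(self, rb357):
        assert rb357.M == 105
        assert rb357.b == 15

    def test_non_coprime_moduli_rejected(self):
        with pytest.raises(ValueError, match="4 and 6"):
            make_residue_base([4, 6], 64, seed=0)

    def test_consecutive_subset_sum_moduli_accepted(self):
        rb = make_residue_base([199, 200, 201], 32, seed=0)
        assert rb.M == 199 * 200 * 201


class TestCrt:
    def test_worked_residue_example(self):
        assert residues_of(20, [3, 5, 7]) == [2, 0, 6]
        assert crt_reconstruct([2, 0, 6], [3, 5, 7]) == 20

    def test_round_trip_exhaustive(self):
        for x in range(105):
            assert crt_reconstruct(residues_of(x, [3, 5, 7]), [3, 5, 7]) == x

    def test_out_of_range_residue_rejected(self):
        with pytest.raises(ValueError):
            crt_reconstruct([3, 0, 0], [3, 5, 7])


class TestAdditiveBinding:
    def test_encoding_periodic_in_M(self, rb357_small):
        for x in (0, 1, 50, -3):
            assert rb357_small.encode(x).exact_equals(rb357_small.encode(x + 105))

    def test_homomorphism_random_pairs(self, rb357_small):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x1, x2 = (int(v) for v in rng.integers(-500, 500, size=2))
            lhs = bind_add(rb357_small.encode(x1), rb357_small.encode(x2))
            assert lhs.exact_equals(rb357_small.encode((x1 + x2) % 105))

    def test_identity_and_inverse(self, rb357_small):
        z = rb357_small.encode(17)
        assert bind_add(z, rb357_small.encode(0)).exact_equals(z)
        assert bind_add(z, additive_inverse(z)).exact_equals(rb357_small.encode(0))

    def test_commutative_and_associative_bit_exact(self, rb357_small):
        a, b, c = (rb357_small.encode(x) for x in (7, 31, 64))
        assert bind_add(a, b).exact_equals(bind_add(b, a))
        assert bind_add(bind_add(a, b), c).exact_equals(bind_add(a, bind_add(b, c)))

    def test_quasi_orthogonality_within_range(self, rb357):
        from residuehd import kernel

        z0 = rb357.encode(40)
        for dx in (1, 2, 17, 52, 104):
            val = float(kernel(rb357.encode(40 + dx), z0))
            assert abs(val) < 5 / np.sqrt(rb357.dim)

    def test_decoded_sum(self, rb357):
        cb = Codebook.from_residue_base(rb357)
        z = bind_add(rb357.encode(2), rb357.encode(3))
        assert codebook_decode(z, cb) == 5


class TestAntiBase:
    def test_worked_inverse_example(self):
        # base whose first component index is 3 (mod 5): inverse must be 2
        base = ModulusBase(5, np.array([3, 1, 2, 4]), nonzero_only=True)
        anti = make_anti_base(base)
        assert anti.inv_indices[0] == 2
        assert anti.inv_indices[1] == 1  # 1 is self-inverse

    def test_all_pairs_m7(self):
        base = ModulusBase(7, np.arange(1, 7), nonzero_only=True)
        anti = make_anti_base(base)
        assert ((base.indices * anti.inv_indices) % 7 == 1).all()

    def test_composite_modulus_rejected(self):
        base = make_modulus_base(6, 32, nonzero_only=True, seed=0)
        with pytest.raises(ValueError, match="prime"):
            make_anti_base(base)

    def test_zero_index_rejected(self):
        base = make_modulus_base(5, 64, nonzero_only=False, seed=4)
        assert (base.indices == 0).any()
        with pytest.raises(ValueError):
            make_anti_base(base)


@pytest.fixture(scope="module")
def antis357(rb357):
    return [make_anti_base(b) for b in rb357.bases]


class TestMultiplicativeBinding:
    def test_decoded_product(self, rb357, antis357):
        cb = Codebook.from_residue_base(rb357)
        z = bind_mult(rb357.encode_factors(2), rb357.encode_factors(3), rb357, antis357)
        assert codebook_decode(z, cb) == 6

    def test_multiplicative_identity(self, rb357, antis357):
        for x in (0, 1, 17, 104):
            z = bind_mult(
                rb357.encode_factors(x), rb357.encode_factors(1), rb357, antis357
            )
            assert z.exact_equals(rb357.encode(x))

    def test_homomorphism_exhaustive_small(self):
        # all pairs in [0, 15)^2 against the integer mod-15 oracle
        rb = make_residue_base([3, 5], 64, nonzero_only=True, seed=5)
        antis = [make_anti_base(b) for b in rb.bases]
        for x1 in range(15):
            f1 = rb.encode_factors(x1)
            for x2 in range(15):
                z = bind_mult(f1, rb.encode_factors(x2), rb, antis)
                assert z.exact_equals(rb.encode((x1 * x2) % 15))

    def test_rational_factor_rejected(self, rb35):
        from residuehd import encode_rational

        antis = [make_anti_base(b) for b in rb35.bases]
        bad = [encode_rational(b, "1/2") for b in rb35.bases]
        with pytest.raises(ValueError):
            bind_mult(bad, rb35.encode_factors(2), rb35, antis)

    def test_off_grid_angle_rejected(self, rb35):
        antis = [make_anti_base(b) for b in rb35.bases]
        bad = [
            PhasorVector(np.exp(1j * (0.1 + np.zeros(rb35.dim))))
            for _ in rb35.bases
        ]
        with pytest.raises(ValueError, match="not an integer encoding"):
            bind_mult(bad, rb35.encode_factors(2), rb35, antis)

    def test_angle_extraction_path(self, rb35):
        # vectors stripped of exact-phase metadata decode via angles
        antis = [make_anti_base(b) for b in rb35.bases]
        f4 = [PhasorVector(z.values.copy()) for z in rb35.encode_factors(4)]
        z = bind_mult(f4, rb35.encode_factors(4), rb35, antis)
        assert z.exact_equals(rb35.encode(1))  # 16 mod 15

    def test_multiply_composed_uses_resonator(self, rb35):
        antis = [make_anti_base(b) for b in rb35.bases]
        z = multiply_composed(rb35.encode(4), rb35.encode(7), rb35, antis, seed=0)
        assert z.exact_equals(rb35.encode(28 % 15))
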