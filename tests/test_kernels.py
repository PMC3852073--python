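"""The string-kernel family: closed forms, oracle agreement, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhc2sk import (
    KernelParams,
    brute_force_kernel,
    encode_peptides,
    gram_matrix,
    gs_kernel,
    mhc2sk_kernel,
    srbf_kernel,
    substring_rbf,
)
from mhc2sk.encoding import STANDARD_RESIDUES
from mhc2sk.kernels import GramMatrix, rect_kernel_matrix

peptide_st = st.text(alphabet=STANDARD_RESIDUES, min_size=1, max_size=16)


# ------------------------------------------------------------- substring RBF

def test_substring_rbf_identity_is_one():
    for sigma_c in (0.5, 1.0, 7.3):
        assert substring_rbf("ACD", "ACD", sigma_c) == 1.0


def test_substring_rbf_single_residue_closed_form(enc):
    assert substring_rbf("A", "R", 1.0) == pytest.approx(math.exp(-enc.sq("A", "R") / 2.0), rel=1e-12)


def test_substring_rbf_large_bandwidth_limit():
    assert substring_rbf("ACDEF", "WYVKL", 1e9) == pytest.approx(1.0, abs=1e-6)


def test_substring_rbf_rejects_unequal_lengths():
    with pytest.raises(ValueError, match="equal lengths"):
        substring_rbf("AC", "ACD", 1.0)


# --------------------------------------------------------------------- SRBF

def test_srbf_single_term_equals_substring_rbf():
    assert srbf_kernel("ACDEF", "WYVKL", 5, 2.0) == pytest.approx(
        substring_rbf("ACDEF", "WYVKL", 2.0), rel=1e-12
    )


def test_srbf_self_full_length_is_one():
    assert srbf_kernel("ACDEFGH", "ACDEFGH", 7, 3.0) == pytest.approx(1.0)


def test_srbf_term_count_limit(rng):
    """With an enormous bandwidth every term tends to 1, so the kernel
    counts substring pairs: (12-9+1)(15-9+1) = 28."""
    y = "".join(rng.choice(list(STANDARD_RESIDUES), size=12))
    y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=15))
    assert srbf_kernel(y, y2, 9, 1e9) == pytest.approx(28.0, abs=1e-4)


def test_srbf_zero_when_peptide_shorter_than_l():
    assert srbf_kernel("ACD", "ACDEF", 4, 1.0) == 0.0


# ----------------------------------------------------------------------- GS

def test_gs_single_residue_identity():
    p = KernelParams(sigma_c=1.0, sigma_p=1.0, L=1)
    assert gs_kernel("A", "A", p) == pytest.approx(1.0)


def test_gs_two_residue_closed_form(enc):
    """Enumerating the four (i, j) pairs for y = y2 = 'AC', L = 1:
    two identical pairs (1) and two cross pairs with penalty exp(-1/2)."""
    p = KernelParams(sigma_c=1.0, sigma_p=1.0, L=1)
    expected = 2.0 + 2.0 * math.exp(-0.5) * math.exp(-enc.sq("A", "C") / 2.0)
    assert gs_kernel("AC", "AC", p) == pytest.approx(expected, rel=1e-12)


def test_gs_term_count_limit(rng):
    """sigma_p, sigma_c -> inf: sum over l=1..3 of (4-l+1)(5-l+1) = 38."""
    y = "".join(rng.choice(list(STANDARD_RESIDUES), size=4))
    y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=5))
    p = KernelParams(sigma_c=1e9, sigma_p=1e9, L=3)
    assert gs_kernel(y, y2, p) == pytest.approx(38.0, abs=1e-3)


# ------------------------------------------------------------------- MHC2SK

def test_mhc2sk_full_length_self_is_one():
    p = KernelParams(sigma_c=2.0, l_min=7)
    assert mhc2sk_kernel("ACDEFGH", "ACDEFGH", p) == pytest.approx(1.0)


def test_mhc2sk_term_count_limit(rng):
    """sigma_c -> inf, lengths 11 and 13, L' = 9: 3*5 + 2*4 + 1*3 = 26."""
    y = "".join(rng.choice(list(STANDARD_RESIDUES), size=11))
    y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=13))
    p = KernelParams(sigma_c=1e9, l_min=9)
    assert mhc2sk_kernel(y, y2, p) == pytest.approx(26.0, abs=1e-3)


def test_mhc2sk_empty_sum_warns_and_returns_zero():
    import mhc2sk.kernels as kmod

    kmod._warned_empty = False
    p = KernelParams(sigma_c=1.0, l_min=9)
    with pytest.warns(UserWarning, match="shorter than l_min"):
        assert mhc2sk_kernel("ACDEF", "ACDEFGHIKL", p) == 0.0


def test_mhc2sk_decomposition(rng):
    """K(L') = K(L'+1) + SRBF(l = L') whenever L' <= min length."""
    for _ in range(10):
        y = "".join(rng.choice(list(STANDARD_RESIDUES), size=rng.integers(6, 13)))
        y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=rng.integers(6, 13)))
        l_min = int(rng.integers(1, min(len(y), len(y2))))
        lhs = mhc2sk_kernel(y, y2, KernelParams(sigma_c=2.0, l_min=l_min))
        rhs = mhc2sk_kernel(y, y2, KernelParams(sigma_c=2.0, l_min=l_min + 1)) + srbf_kernel(
            y, y2, l_min, 2.0
        )
        assert lhs == pytest.approx(rhs, rel=1e-10)


def test_mhc2sk_monotone_in_l_min(rng):
    y = "".join(rng.choice(list(STANDARD_RESIDUES), size=12))
    y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=10))
    vals = [mhc2sk_kernel(y, y2, KernelParams(sigma_c=2.0, l_min=l)) for l in range(1, 11)]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_mhc2sk_self_diagonal_lower_bound(rng):
    """The i = j terms each equal 1, so K(y,y) >= sum_l (|y|-l+1)."""
    y = "".join(rng.choice(list(STANDARD_RESIDUES), size=11))
    for l_min in (1, 5, 9):
        lower = sum(len(y) - l + 1 for l in range(l_min, len(y) + 1))
        assert mhc2sk_kernel(y, y, KernelParams(sigma_c=0.4, l_min=l_min)) >= lower


def test_gs_limit_equals_mhc2sk_lmin_one(rng):
    """Without its positional penalty and with the full length range, GS on
    equal-length peptides is the L' = 1 case of MHC2SK."""
    for _ in range(5):
        n = int(rng.integers(5, 12))
        y = "".join(rng.choice(list(STANDARD_RESIDUES), size=n))
        y2 = "".join(rng.choice(list(STANDARD_RESIDUES), size=n))
        gs = gs_kernel(y, y2, KernelParams(sigma_c=2.0, sigma_p=1e6, L=n))
        mk = mhc2sk_kernel(y, y2, KernelParams(sigma_c=2.0, l_min=1))
        assert gs == pytest.approx(mk, rel=1e-6)


# ------------------------------------------------------------------ symmetry

@settings(deadline=None, max_examples=25)
@given(y=peptide_st, y2=peptide_st, data=st.data())
def test_kernels_are_symmetric(y, y2, data):
    sigma_c = data.draw(st.floats(0.5, 10.0))
    p = KernelParams(sigma_c=sigma_c, sigma_p=1.5, L=4, l_min=2)
    assert srbf_kernel(y, y2, 2, sigma_c) == pytest.approx(srbf_kernel(y2, y, 2, sigma_c), abs=1e-12, rel=1e-12)
    assert gs_kernel(y, y2, p) == pytest.approx(gs_kernel(y2, y, p), abs=1e-12, rel=1e-12)
    assert mhc2sk_kernel(y, y2, p) == pytest.approx(mhc2sk_kernel(y2, y, p), abs=1e-12, rel=1e-12)


# ----------------------------------------------------------- oracle agreement

def test_fast_kernels_match_brute_force_oracle(rng):
    """The production path (prefix/recurrence algebra, batching) must agree
    with the literal nested-loop evaluation to 1e-10 relative."""
    residues = list(STANDARD_RESIDUES)
    for _ in range(25):
        y = "".join(rng.choice(residues, size=rng.integers(4, 15)))
        y2 = "".join(rng.choice(residues, size=rng.integers(4, 15)))
        params = KernelParams(
            sigma_c=float(rng.uniform(0.5, 5.0)),
            sigma_p=float(rng.uniform(0.5, 15.0)),
            L=int(rng.integers(1, 8)),
            l_min=int(rng.integers(1, 6)),
            srbf_length=int(rng.integers(1, 6)),
        )
        for name, fast in [
            ("srbf", srbf_kernel(y, y2, params.srbf_length, params.sigma_c)),
            ("gs", gs_kernel(y, y2, params)),
            ("mhc2sk", mhc2sk_kernel(y, y2, params)),
        ]:
            oracle = brute_force_kernel(y, y2, name, params)
            assert fast == pytest.approx(oracle, rel=1e-10, abs=1e-12), name


# ----------------------------------------------------------------- Gram matrix

def test_gram_single_peptide():
    g = gram_matrix(["ACDEFGHIK"], "mhc2sk", KernelParams(sigma_c=2.0, l_min=3))
    assert g.values.shape == (1, 1)
    assert g.values[0, 0] > 0


def test_gram_normalized_unit_diagonal(small_peptides):
    g = gram_matrix(small_peptides, "mhc2sk", KernelParams(sigma_c=2.0, l_min=3), normalize=True)
    assert np.allclose(np.diag(g.values), 1.0)
    assert g.normalized


def test_gram_matches_pairwise_kernel(small_peptides):
    p = KernelParams(sigma_c=2.0, l_min=3)
    g = gram_matrix(small_peptides, "mhc2sk", p)
    for i in (0, 3, 7):
        for j in (1, 5, 11):
            assert g.values[i, j] == pytest.approx(
                mhc2sk_kernel(small_peptides[i], small_peptides[j], p), rel=1e-10
            )


@pytest.mark.parametrize("l_min", [1, 3, 9])
def test_gram_positive_semidefinite(small_peptides, l_min):
    g = gram_matrix(small_peptides, "mhc2sk", KernelParams(sigma_c=2.0, l_min=l_min))
    eig = np.linalg.eigvalsh(g.values)
    assert eig.min() >= -1e-8 * eig.max()


def test_gram_annotates_offending_item(small_peptides):
    with pytest.raises(Exception, match="item 2"):
        gram_matrix(small_peptides[:2] + ["ACXDE"], "mhc2sk", KernelParams())


def test_gram_invariant_validation():
    with pytest.raises(ValueError, match="symmetric"):
        GramMatrix(items=["a", "b"], values=np.array([[1.0, 0.5], [0.2, 1.0]]),
                   params=KernelParams(), kernel_name="mhc2sk")


def test_rect_matrix_consistent_with_square(small_peptides, enc):
    p = KernelParams(sigma_c=2.0, l_min=2)
    peps = encode_peptides(small_peptides, enc)
    square = gram_matrix(small_peptides, "mhc2sk", p).values
    rect = rect_kernel_matrix(peps[:5], peps, "mhc2sk", p)
    assert np.allclose(rect, square[:5], atol=1e-10)
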