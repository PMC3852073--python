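"""String kernels for variable-length peptides.

Three related kernels are implemented, all built from one primitive: the RBF
similarity of two equal-length substrings under a residue encoding phi,

    k_l(s, s') = exp( - sum_i ||phi(s_i) - phi(s'_i)||^2 / (2 sigma_c^2) ).

* SRBF (spectrum RBF): sum of k_l over all substring pairs of one fixed
  length l.
* GS (generic string kernel): sum over lengths 1..L of all substring pairs,
  each weighted by a Gaussian penalty exp(-(i-j)^2 / (2 sigma_p^2)) on the
  difference of the two start positions.
* MHC2SK: sum over lengths from a *minimum* L' up to the shorter peptide's
  length, with no positional penalty.  Long substring matches are what carry
  signal for MHC class II binding (the bound nonamer core can sit anywhere in
  an 11-20 residue peptide, so a start-position penalty is counterproductive);
  MHC2SK drops the penalty and discards short, noisy substring lengths
  instead.  Being a sum of SRBF kernels it is positive semi-definite.

Fast evaluation uses a multiplicative recurrence over substring length on the
matrix of per-position residue similarities; a literal nested-loop oracle
(:func:`brute_force_kernel`) guards the algebra in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import AlphabetEncoding, EncodedPeptide, load_blosum62_encoding

KERNEL_NAMES = ("srbf", "gs", "mhc2sk", "mhc2skpan")


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the kernel family.

    Parameters
    ----------
    sigma_c : float
        Bandwidth of the per-substring RBF on encoded residues.  Scales the
        BLOSUM62 squared distances (which are O(10-100) per position) into
        the exponent.
    sigma_p : float
        GS-only Gaussian penalty bandwidth on the start-position difference.
        ``inf`` disables the penalty.
    L : int
        GS-only maximum substring length.
    l_min : int
        MHC2SK minimum substring length (the L' parameter); substrings of
        every length from ``l_min`` up to the shorter peptide are compared.
    sigma_a : float
        Bandwidth of the allele (pseudosequence) RBF kernel in the
        pan-specific product kernel.
    srbf_length : int
        SRBF-only fixed substring length l.
    """

    sigma_c: float = 5.0
    sigma_p: float = 1.0
    L: int = 10
    l_min: int = 9
    sigma_a: float = 6.5
    srbf_length: int = 9

    def __post_init__(self):
        if self.sigma_c <= 0:
            raise ValueError(f"sigma_c must be positive, got {self.sigma_c}")
        if self.sigma_p <= 0:
            raise ValueError(f"sigma_p must be positive, got {self.sigma_p}")
        if self.sigma_a <= 0:
            raise ValueError(f"sigma_a must be positive, got {self.sigma_a}")
        for name in ("L", "l_min", "srbf_length"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")


@dataclass
class GramMatrix:
    """A symmetric kernel matrix with provenance of what produced it."""

    items: list
    values: np.ndarray
    params: KernelParams
    kernel_name: str
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.items):
            raise ValueError("Gram matrix shape does not match item list")
        if not np.all(np.isfinite(v)):
            raise ValueError("Gram matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("Gram matrix is not symmetric")
        if np.any(np.diag(v) <= 0):
            raise ValueError("Gram matrix diagonal must be strictly positive")
        self.values = v


def _as_encoded(y, enc: AlphabetEncoding | None = None) -> EncodedPeptide:
    if isinstance(y, EncodedPeptide):
        return y
    from .encoding import encode_peptide

    return encode_peptide(y, enc)


# ---------------------------------------------------------------------------
# single-pair kernels
# ---------------------------------------------------------------------------

def substring_rbf(s, s2, sigma_c: float, enc: AlphabetEncoding | None = None) -> float:
    """RBF similarity of two equal-length (sub)strings; 1 iff identical."""
    s, s2 = _as_encoded(s, enc), _as_encoded(s2, enc)
    if len(s) != len(s2):
        raise ValueError(f"substring_rbf requires equal lengths, got {len(s)} and {len(s2)}")
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    sq = s.encoding.sq_dist
    total = float(sq[s.idx, s2.idx].sum())
    return float(np.exp(-total / (2.0 * sigma_c * sigma_c)))


def _pair_core(a_idx, b_idx, sq, sigma_c, l_min, l_max, sigma_p=None) -> float:
    """Shared fast path: sum over lengths l_min..l_max of all substring-pair
    RBF terms, optionally position-penalised (GS).

    Uses E_{l+1}[i,j] = E_l[i,j] * E_1[i+l, j+l] where E_1 is the matrix of
    single-residue similarities, so only |y|*|y2| exponentials are taken.
    """
    n, m = len(a_idx), len(b_idx)
    l_hi = min(n, m, l_max)
    if l_hi < l_min:
        return 0.0
    E1 = np.exp(-sq[np.ix_(a_idx, b_idx)] / (2.0 * sigma_c * sigma_c))
    pen = None
    if sigma_p is not None and np.isfinite(sigma_p):
        d = np.arange(n)[:, None] - np.arange(m)[None, :]
        pen = np.exp(-(d * d) / (2.0 * sigma_p * sigma_p))
    total = 0.0
    E = E1
    for l in range(1, l_hi + 1):
        if l >= l_min:
            if pen is not None:
                total += float((E * pen[: n - l + 1, : m - l + 1]).sum())
            else:
                total += float(E.sum())
        if l < l_hi:
            E = E[:-1, :-1] * E1[l:, l:]
    return total


def srbf_kernel(y, y2, l: int, sigma_c: float, enc=None) -> float:
    """Spectrum-RBF kernel: substring RBF summed over all pairs of length-l
    substrings.  Zero (empty sum) when either peptide is shorter than l."""
    y, y2 = _as_encoded(y, enc), _as_encoded(y2, enc)
    if l < 1 or int(l) != l:
        raise ValueError(f"substring length must be an integer >= 1, got {l}")
    return _pair_core(y.idx, y2.idx, y.encoding.sq_dist, sigma_c, l, l)


def gs_kernel(y, y2, params: KernelParams, enc=None) -> float:
    """Generic string kernel: lengths 1..L, Gaussian start-position penalty.

    Lengths exceeding the shorter peptide contribute empty sums.
    """
    y, y2 = _as_encoded(y, enc), _as_encoded(y2, enc)
    return _pair_core(
        y.idx, y2.idx, y.encoding.sq_dist, params.sigma_c, 1, params.L, sigma_p=params.sigma_p
    )


_warned_empty = False


def mhc2sk_kernel(y, y2, params: KernelParams, enc=None) -> float:
    """MHC2SK kernel: substring lengths from l_min (L') up to min(|y|,|y2|),
    no positional penalty.

    When the shorter peptide is below ``l_min`` the sum is empty and the
    kernel is 0 (warned once per run); with peptides of 11+ residues and
    L' <= 9 this never happens in normal use.
    """
    y, y2 = _as_encoded(y, enc), _as_encoded(y2, enc)
    if min(len(y), len(y2)) < params.l_min:
        global _warned_empty
        if not _warned_empty:
            warnings.warn(
                "MHC2SK evaluated on a peptide shorter than l_min; returning 0 (empty sum)",
                stacklevel=2,
            )
            _warned_empty = True
        return 0.0
    return _pair_core(y.idx, y2.idx, y.encoding.sq_dist, params.sigma_c, params.l_min, min(len(y), len(y2)))


# ---------------------------------------------------------------------------
# batched Gram computation
# ---------------------------------------------------------------------------

_CHUNK_ELEMS = 4_000_000  # cap on B*n*m per batch to bound memory


def _grouped_pair_values(
    peps1: Sequence[EncodedPeptide],
    peps2: Sequence[EncodedPeptide],
    pi: np.ndarray,
    pj: np.ndarray,
    exp_table: np.ndarray,
    l_min: int,
    l_max: int | None = None,
    sigma_p: float | None = None,
    stack_l: int | None = None,
) -> np.ndarray:
    """Kernel values for explicit index pairs (pi[p] from peps1, pj[p] from peps2).

    Pairs are grouped by their (length, length) signature so that each group
    is evaluated as one vectorised batch.  Returns shape (npairs,) or, when
    ``stack_l`` is given, (stack_l, npairs) with row l-1 holding the fixed-
    length-l (SRBF) contribution so callers can form any suffix sum.
    """
    npairs = len(pi)
    if npairs == 0:
        return np.zeros((stack_l, 0)) if stack_l is not None else np.zeros(0)
    if stack_l is not None:
        out = np.zeros((stack_l, npairs))
    else:
        out = np.zeros(npairs)
    lens1 = np.array([len(p) for p in peps1])
    lens2 = np.array([len(p) for p in peps2])
    keys = lens1[pi] * 100_000 + lens2[pj]
    order = np.argsort(keys, kind="stable")
    bounds = np.flatnonzero(np.r_[True, np.diff(keys[order]) != 0, True])
    for g0, g1 in zip(bounds[:-1], bounds[1:]):
        sel = order[g0:g1]
        n = int(lens1[pi[sel[0]]])
        m = int(lens2[pj[sel[0]]])
        l_hi = min(n, m, l_max if l_max is not None else min(n, m))
        if stack_l is not None:
            l_hi = min(l_hi, stack_l)
        if l_hi < l_min:
            continue
        pen = None
        if sigma_p is not None and np.isfinite(sigma_p):
            d = np.arange(n)[:, None] - np.arange(m)[None, :]
            pen = np.exp(-(d * d) / (2.0 * sigma_p * sigma_p))
        chunk = max(1, _CHUNK_ELEMS // (n * m))
        for c0 in range(0, len(sel), chunk):
            csel = sel[c0 : c0 + chunk]
            A = np.stack([peps1[k].idx for k in pi[csel]])
            B = np.stack([peps2[k].idx for k in pj[csel]])
            E1 = exp_table[A[:, :, None], B[:, None, :]]
            E = E1
            acc = np.zeros(len(csel)) if stack_l is None else None
            for l in range(1, l_hi + 1):
                if l >= l_min:
                    term = E * pen[: n - l + 1, : m - l + 1] if pen is not None else E
                    vals = term.sum(axis=(1, 2))
                    if stack_l is not None:
                        out[l - 1, csel] = vals
                    else:
                        acc += vals
                if l < l_hi:
                    E = E[:, :-1, :-1] * E1[:, l:, l:]
            if stack_l is None:
                out[csel] = acc
    return out


def _square_from_pairs(n_items: int, pair_values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(n_items)
    K = np.zeros((n_items, n_items))
    K[iu] = pair_values
    K[(iu[1], iu[0])] = pair_values
    return K


def srbf_gram_stack(
    peptides: Sequence[EncodedPeptide], sigma_c: float, l_max: int
) -> np.ndarray:
    """Per-length SRBF Gram stack, shape (l_max, N, N): layer l-1 is the
    SRBF Gram at fixed substring length l.

    MHC2SK Grams for every choice of l_min are suffix sums over layers, so a
    grid search over l_min costs one stack per sigma_c.
    """
    n = len(peptides)
    enc = peptides[0].encoding
    iu = np.triu_indices(n)
    vals = _grouped_pair_values(
        peptides, peptides, iu[0], iu[1], enc.exp_table(sigma_c), 1, l_max, stack_l=l_max
    )
    return np.stack([_square_from_pairs(n, vals[l]) for l in range(l_max)])


def cosine_normalize(K: np.ndarray) -> np.ndarray:
    """K(a,b) / sqrt(K(a,a) K(b,b)); requires a strictly positive diagonal."""
    d = np.sqrt(np.diag(K))
    if np.any(d <= 0):
        raise ValueError("cosine normalization requires strictly positive diagonal")
    return K / np.outer(d, d)


def _peptide_gram_values(peptides, kernel_name, params) -> np.ndarray:
    n = len(peptides)
    enc = peptides[0].encoding
    T = enc.exp_table(params.sigma_c)
    iu = np.triu_indices(n)
    name = kernel_name.lower()
    if name == "srbf":
        vals = _grouped_pair_values(
            peptides, peptides, iu[0], iu[1], T, params.srbf_length, params.srbf_length
        )
    elif name == "gs":
        vals = _grouped_pair_values(
            peptides, peptides, iu[0], iu[1], T, 1, params.L, sigma_p=params.sigma_p
        )
    elif name == "mhc2sk":
        vals = _grouped_pair_values(peptides, peptides, iu[0], iu[1], T, params.l_min, None)
    else:
        raise ValueError(f"unknown peptide kernel {kernel_name!r}")
    return _square_from_pairs(n, vals)


def gram_matrix(
    peptides: Sequence,
    kernel_name: str,
    params: KernelParams,
    normalize: bool = False,
    enc: AlphabetEncoding | None = None,
) -> GramMatrix:
    """Symmetric kernel matrix over a peptide list (upper triangle computed,
    then mirrored).  ``normalize`` applies cosine normalization, giving a
    unit diagonal."""
    if len(peptides) == 0:
        raise ValueError("gram_matrix requires a non-empty peptide list")
    if enc is None:
        enc = load_blosum62_encoding()
    encoded = []
    for i, p in enumerate(peptides):
        try:
            encoded.append(_as_encoded(p, enc))
        except Exception as exc:
            raise type(exc)(f"item {i}: {exc}") from exc
    K = _peptide_gram_values(encoded, kernel_name, params)
    if normalize:
        K = cosine_normalize(K)
    return GramMatrix(
        items=[p.seq for p in encoded],
        values=K,
        params=params,
        kernel_name=kernel_name.lower(),
        normalized=normalize,
    )


def rect_kernel_matrix(
    peps_a: Sequence[EncodedPeptide],
    peps_b: Sequence[EncodedPeptide],
    kernel_name: str,
    params: KernelParams,
) -> np.ndarray:
    """Rectangular (test x train) kernel matrix, unnormalized."""
    na, nb = len(peps_a), len(peps_b)
    enc = peps_a[0].encoding
    T = enc.exp_table(params.sigma_c)
    pi, pj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    pi, pj = pi.ravel(), pj.ravel()
    name = kernel_name.lower()
    if name == "srbf":
        vals = _grouped_pair_values(peps_a, peps_b, pi, pj, T, params.srbf_length, params.srbf_length)
    elif name == "gs":
        vals = _grouped_pair_values(peps_a, peps_b, pi, pj, T, 1, params.L, sigma_p=params.sigma_p)
    elif name == "mhc2sk":
        vals = _grouped_pair_values(peps_a, peps_b, pi, pj, T, params.l_min, None)
    else:
        raise ValueError(f"unknown peptide kernel {kernel_name!r}")
    return vals.reshape(na, nb)


def self_kernel_values(peptides, kernel_name, params) -> np.ndarray:
    """K(y, y) for each peptide (needed to normalize rectangular matrices)."""
    n = len(peptides)
    enc = peptides[0].encoding
    T = enc.exp_table(params.sigma_c)
    idx = np.arange(n)
    name = kernel_name.lower()
    if name == "srbf":
        return _grouped_pair_values(peptides, peptides, idx, idx, T, params.srbf_length, params.srbf_length)
    if name == "gs":
        return _grouped_pair_values(peptides, peptides, idx, idx, T, 1, params.L, sigma_p=params.sigma_p)
    if name == "mhc2sk":
        return _grouped_pair_values(peptides, peptides, idx, idx, T, params.l_min, None)
    raise ValueError(f"unknown peptide kernel {kernel_name!r}")


# ---------------------------------------------------------------------------
# brute-force oracle (tests only; literal nested loops, no shared algebra)
# ---------------------------------------------------------------------------

def brute_force_kernel(y, y2, kernel_name: str, params: KernelParams, enc=None) -> float:
    """Evaluate SRBF/GS/MHC2SK by literal nested loops over every substring
    pair at every admissible length.  O(n * m * l) per length; intended for
    peptides of length <= ~25 in tests."""
    import math

    y, y2 = _as_encoded(y, enc), _as_encoded(y2, enc)
    sq = y.encoding.sq_dist
    a, b = y.idx, y2.idx
    n, m = len(a), len(b)
    name = kernel_name.lower()
    if name == "srbf":
        lengths = [params.srbf_length]
        penalised = False
    elif name == "gs":
        lengths = list(range(1, params.L + 1))
        penalised = True
    elif name == "mhc2sk":
        lengths = list(range(params.l_min, min(n, m) + 1))
        penalised = False
    else:
        raise ValueError(f"unknown kernel {kernel_name!r}")
    total = 0.0
    for l in lengths:
        for i in range(n - l + 1):
            for j in range(m - l + 1):
                s = 0.0
                for k in range(l):
                    s += sq[a[i + k], b[j + k]]
                term = math.exp(-s / (2.0 * params.sigma_c ** 2))
                if penalised:
                    term *= math.exp(-((i - j) ** 2) / (2.0 * params.sigma_p ** 2))
                total += term
    return total
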