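"""Amino-acid alphabet handling and the BLOSUM62 residue encoding.

Every peptide kernel in this package compares residues through an encoding
function phi that maps each of the 20 standard amino acids to a d-dimensional
real vector.  The shipped default is the raw BLOSUM62 substitution row
(d = 20, integer half-bit scores treated as reals, no normalisation), which
is the convention in spectrum-RBF string-kernel work.  Any whitespace-
separated substitution-style table with a residue header row can be
substituted via :func:`load_encoding_table`.

What the kernels actually consume is the table of pairwise squared distances
``||phi(a) - phi(b)||^2``, precomputed here once for all 400 ordered residue
pairs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

#: Canonical order of the 20 standard amino acids (NCBI substitution-matrix order).
STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"


class EncodingError(ValueError):
    """Raised for corrupt encoding tables or non-encodable peptides."""


@dataclass(frozen=True)
class AlphabetEncoding:
    """A residue -> vector encoding with precomputed squared distances.

    Attributes
    ----------
    residues : str
        The 20 standard one-letter codes, in canonical order.
    vectors : ndarray of shape (20, d)
        Row ``i`` is phi(residues[i]).
    sq_dist : ndarray of shape (20, 20)
        ``sq_dist[i, j] = ||vectors[i] - vectors[j]||**2``.
    """

    residues: str
    vectors: np.ndarray
    sq_dist: np.ndarray
    index: dict = field(repr=False, default_factory=dict)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, residue: str) -> np.ndarray:
        """phi(residue) as a length-d vector."""
        return self.vectors[self.index[residue.upper()]]

    def sq(self, a: str, b: str) -> float:
        """Squared encoding distance between two residues."""
        return float(self.sq_dist[self.index[a.upper()], self.index[b.upper()]])

    def exp_table(self, sigma: float) -> np.ndarray:
        """``exp(-sq_dist / (2 sigma^2))`` over all residue pairs."""
        if sigma <= 0:
            raise ValueError(f"bandwidth must be positive, got {sigma}")
        return np.exp(-self.sq_dist / (2.0 * sigma * sigma))


def _build_encoding(residues: str, vectors: np.ndarray) -> AlphabetEncoding:
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] != len(residues):
        raise EncodingError("encoding table shape does not match residue list")
    diff = vectors[:, None, :] - vectors[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    index = {r: i for i, r in enumerate(residues)}
    return AlphabetEncoding(residues=residues, vectors=vectors, sq_dist=sq, index=index)


def load_encoding_table(path: str | Path) -> AlphabetEncoding:
    """Load a residue->vector encoding from a substitution-matrix-style file.

    The expected layout is the standard NCBI one: optional ``#`` comment
    lines, a header row of single-letter residue codes, then one row per
    residue starting with its letter.  Rows and columns for codes outside
    the 20 standard residues (B, Z, X, ``*`` ...) are ignored; each kept
    row, restricted to the 20 standard columns, becomes phi for that residue.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise EncodingError(f"empty encoding table: {path}")
    header = lines[0].split()
    if any(len(h) != 1 for h in header):
        raise EncodingError(f"malformed header row in {path}")
    try:
        keep_cols = [header.index(r) for r in STANDARD_RESIDUES]
    except ValueError as exc:
        raise EncodingError(f"encoding table {path} lacks a standard residue column: {exc}") from exc
    rows: dict[str, list[float]] = {}
    for ln in lines[1:]:
        parts = ln.split()
        code, values = parts[0], parts[1:]
        if code not in STANDARD_RESIDUES:
            continue
        if len(values) < len(header):
            raise EncodingError(f"row for {code!r} in {path} has {len(values)} entries, expected {len(header)}")
        rows[code] = [float(values[c]) for c in keep_cols]
    missing = [r for r in STANDARD_RESIDUES if r not in rows]
    if missing:
        raise EncodingError(f"encoding table {path} is missing rows for residues {missing}")
    vectors = np.array([rows[r] for r in STANDARD_RESIDUES], dtype=float)
    return _build_encoding(STANDARD_RESIDUES, vectors)


@lru_cache(maxsize=1)
def load_blosum62_encoding() -> AlphabetEncoding:
    """The bundled BLOSUM62 encoding: phi(a) is the raw 20-entry BLOSUM62 row of a."""
    ref = importlib.resources.files("mhc2sk.data").joinpath("blosum62.txt")
    with importlib.resources.as_file(ref) as path:
        if not path.exists():
            raise EncodingError("bundled BLOSUM62 table is missing")
        return load_encoding_table(path)


@dataclass(frozen=True)
class EncodedPeptide:
    """A peptide plus its residue indices into an :class:`AlphabetEncoding`.

    Supports ``len()`` and slicing (a slice is itself an EncodedPeptide, so
    substrings can be fed back into kernels).
    """

    seq: str
    idx: np.ndarray
    encoding: AlphabetEncoding = field(repr=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, key) -> "EncodedPeptide":
        if not isinstance(key, slice):
            raise TypeError("EncodedPeptide supports slicing only")
        return EncodedPeptide(seq=self.seq[key], idx=self.idx[key], encoding=self.encoding)

    @property
    def vectors(self) -> np.ndarray:
        """Per-position encoding vectors, shape (len, d)."""
        return self.encoding.vectors[self.idx]


def encode_peptide(seq: str, enc: AlphabetEncoding | None = None) -> EncodedPeptide:
    """Apply the encoding position-wise to a peptide sequence.

    Input is case-insensitive and normalised to uppercase.  Any character
    outside the 20 standard residues is rejected with its (1-based) position;
    callers wanting a drop-the-record policy handle that at the dataset layer
    (see :func:`mhc2sk.io.read_binding_tsv`).
    """
    if enc is None:
        enc = load_blosum62_encoding()
    if not seq:
        raise EncodingError("empty peptide sequence")
    seq = seq.upper()
    idx = np.empty(len(seq), dtype=np.intp)
    for pos, ch in enumerate(seq):
        i = enc.index.get(ch)
        if i is None:
            raise EncodingError(
                f"non-standard residue {ch!r} at position {pos + 1} in peptide {seq!r}"
            )
        idx[pos] = i
    return EncodedPeptide(seq=seq, idx=idx, encoding=enc)


def encode_peptides(seqs, enc: AlphabetEncoding | None = None) -> list[EncodedPeptide]:
    """Encode a sequence of peptides under the strict residue policy."""
    if enc is None:
        enc = load_blosum62_encoding()
    return [encode_peptide(s, enc) for s in seqs]
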