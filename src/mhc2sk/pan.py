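"""Pan-specific extension: allele pseudosequences and the product kernel.

An MHC class II allele is represented by its pseudosequence — the fixed-length
string (21 residues by default) of polymorphic positions in potential contact
with the bound peptide.  Since pseudosequences share one length, an RBF kernel
on their position-wise encoding distances (bandwidth sigma_a) measures allele
similarity directly.  The pan-specific kernel on (allele, peptide) pairs is
the product

    K((x, y), (x', y')) = K_allele(x, x') * K_MHC2SK(y, y'),

which lets one model pool binding data across alleles: sigma_a controls how
far information is shared (large sigma_a pools everything; small sigma_a
restricts to near-identical pseudosequences).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .encoding import AlphabetEncoding, EncodedPeptide, encode_peptide, load_blosum62_encoding
from .kernels import (
    GramMatrix,
    KernelParams,
    cosine_normalize,
    rect_kernel_matrix,
    self_kernel_values,
    substring_rbf,
    _peptide_gram_values,
)

_ALLELE_RE = re.compile(r"^(?:HLA-)?([A-Z]+[0-9]*)[\*_]?(\d{2}):?(\d{2,3})$")


def normalize_allele_name(name: str) -> str:
    """Canonicalise an HLA allele name to colon-delimited nomenclature.

    ``DRB1_0101``, ``DRB1*0101`` and ``DRB1*01:01`` all map to
    ``DRB1*01:01``.  Names that do not look like HLA alleles are returned
    upper-cased and otherwise untouched (synthetic allele labels pass
    through).
    """
    name = name.strip().upper()
    m = _ALLELE_RE.match(name)
    if m:
        locus, g1, g2 = m.groups()
        return f"{locus}*{g1}:{g2}"
    return name


@dataclass(frozen=True)
class AllelePseudosequence:
    """An allele identifier plus its fixed-length pseudosequence."""

    allele_name: str
    peptide: EncodedPeptide  # the encoded pseudosequence

    @property
    def pseudoseq(self) -> str:
        return self.peptide.seq

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class PseudosequenceSet:
    """A collection of allele pseudosequences of one common length."""

    entries: dict = field(default_factory=dict)  # name -> AllelePseudosequence

    @property
    def length(self) -> int:
        first = next(iter(self.entries.values()))
        return len(first)

    def __contains__(self, name) -> bool:
        return normalize_allele_name(name) in self.entries

    def __getitem__(self, name) -> AllelePseudosequence:
        key = normalize_allele_name(name)
        if key not in self.entries:
            raise KeyError(f"unknown allele {name!r} (normalized: {key!r})")
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list:
        return list(self.entries)

    def add(self, name: str, seq: str, enc: AlphabetEncoding) -> None:
        key = normalize_allele_name(name)
        pep = encode_peptide(seq, enc)
        if self.entries:
            if len(pep) != self.length:
                raise ValueError(
                    f"pseudosequence for {key} has length {len(pep)}, expected {self.length}"
                )
            if key in self.entries:
                if self.entries[key].pseudoseq != pep.seq:
                    raise ValueError(f"duplicate allele {key} with differing pseudosequences")
                warnings.warn(f"duplicate identical pseudosequence entry for {key}; deduplicated")
                return
        self.entries[key] = AllelePseudosequence(allele_name=key, peptide=pep)


def load_pseudosequences(path: str | Path, enc: AlphabetEncoding | None = None) -> PseudosequenceSet:
    """Read pseudosequences from FASTA (header = allele name) or two-column
    whitespace-separated text; allele names are normalized, entries
    deduplicated, and a single common length enforced."""
    if enc is None:
        enc = load_blosum62_encoding()
    path = Path(path)
    text = path.read_text()
    coll = PseudosequenceSet()
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not stripped:
        raise ValueError(f"empty pseudosequence file: {path}")
    if stripped[0].lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            coll.add(rec.id, str(rec.seq), enc)
    else:
        for ln in stripped:
            parts = ln.split()
            if len(parts) < 2:
                raise ValueError(f"malformed pseudosequence line: {ln!r}")
            coll.add(parts[0], parts[1], enc)
    return coll


def write_pseudosequences(coll: PseudosequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in coll.entries.values():
            fh.write(f"{entry.allele_name}\t{entry.pseudoseq}\n")


@dataclass(frozen=True)
class AllelePeptidePair:
    """An (allele, peptide) item, optionally with a measured affinity."""

    allele: AllelePseudosequence
    peptide: EncodedPeptide
    affinity: float | None = None


def allele_kernel(x: AllelePseudosequence, x2: AllelePseudosequence, sigma_a: float) -> float:
    """RBF kernel on two full pseudosequences (single term of length P)."""
    return substring_rbf(x.peptide, x2.peptide, sigma_a)


def mhc2skpan_kernel(p: AllelePeptidePair, p2: AllelePeptidePair, params: KernelParams) -> float:
    """Product of the allele RBF kernel and the MHC2SK peptide kernel."""
    from .kernels import mhc2sk_kernel

    return allele_kernel(p.allele, p2.allele, params.sigma_a) * mhc2sk_kernel(
        p.peptide, p2.peptide, params
    )


# ---------------------------------------------------------------------------
# vectorised Gram assembly for (allele, peptide) item lists
# ---------------------------------------------------------------------------

def allele_kernel_matrix(
    seqs_a: Sequence[AllelePseudosequence],
    seqs_b: Sequence[AllelePseudosequence],
    sigma_a: float,
) -> np.ndarray:
    """Allele RBF kernel matrix between two pseudosequence lists."""
    enc = seqs_a[0].peptide.encoding
    A = np.stack([s.peptide.idx for s in seqs_a])
    B = np.stack([s.peptide.idx for s in seqs_b])
    D = enc.sq_dist[A[:, None, :], B[None, :, :]].sum(axis=2)
    return np.exp(-D / (2.0 * sigma_a * sigma_a))


def _resolve_items(
    items: Iterable,
    pseudoseqs: PseudosequenceSet,
    enc: AlphabetEncoding,
) -> tuple[list[AllelePseudosequence], list[EncodedPeptide]]:
    alleles, peptides = [], []
    for it in items:
        if isinstance(it, AllelePeptidePair):
            alleles.append(it.allele)
            peptides.append(it.peptide)
        else:
            name, pep = it
            alleles.append(pseudoseqs[name])
            peptides.append(pep if isinstance(pep, EncodedPeptide) else encode_peptide(pep, enc))
    return alleles, peptides


def pan_gram(
    items: Sequence,
    pseudoseqs: PseudosequenceSet,
    params: KernelParams,
    normalize: bool = False,
    enc: AlphabetEncoding | None = None,
) -> GramMatrix:
    """MHC2SKpan Gram matrix over (allele, peptide) items.

    The allele factor is computed over the distinct alleles and broadcast
    (items from one dataset repeat few alleles over many peptides), then
    multiplied elementwise with the MHC2SK peptide Gram.  Cosine
    normalization of the product equals the product of the normalized
    factors, so one flag governs both.
    """
    if enc is None:
        enc = load_blosum62_encoding()
    alleles, peptides = _resolve_items(items, pseudoseqs, enc)
    names = [a.allele_name for a in alleles]
    uniq = sorted(set(names))
    pos = {n: i for i, n in enumerate(uniq)}
    uniq_seqs = [next(a for a in alleles if a.allele_name == n) for n in uniq]
    Ka_u = allele_kernel_matrix(uniq_seqs, uniq_seqs, params.sigma_a)
    amap = np.array([pos[n] for n in names])
    Ka = Ka_u[np.ix_(amap, amap)]
    Kp = _peptide_gram_values(peptides, "mhc2sk", params)
    K = Ka * Kp
    if normalize:
        K = cosine_normalize(K)
    item_ids = [f"{n}/{p.seq}" for n, p in zip(names, peptides)]
    return GramMatrix(items=item_ids, values=K, params=params, kernel_name="mhc2skpan", normalized=normalize)


def pan_rect_matrix(
    items_a: Sequence,
    items_b: Sequence,
    pseudoseqs: PseudosequenceSet,
    params: KernelParams,
    enc: AlphabetEncoding | None = None,
) -> np.ndarray:
    """Rectangular (test x train) MHC2SKpan kernel matrix, unnormalized."""
    if enc is None:
        enc = load_blosum62_encoding()
    al_a, pep_a = _resolve_items(items_a, pseudoseqs, enc)
    al_b, pep_b = _resolve_items(items_b, pseudoseqs, enc)
    Ka = allele_kernel_matrix(al_a, al_b, params.sigma_a)
    Kp = rect_kernel_matrix(pep_a, pep_b, "mhc2sk", params)
    return Ka * Kp


def pan_self_values(items, pseudoseqs, params, enc=None) -> np.ndarray:
    """K(z, z) for each (allele, peptide) item (allele factor is 1)."""
    if enc is None:
        enc = load_blosum62_encoding()
    _, peptides = _resolve_items(items, pseudoseqs, enc)
    return self_kernel_values(peptides, "mhc2sk", params)
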