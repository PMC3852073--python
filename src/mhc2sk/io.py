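"""Dataset containers and TSV readers/writers.

The native dataset dialect is a three-column TSV (allele, peptide, value)
with an optional, auto-detected header, mirroring the layout of the public
MHC-II benchmark files.  The value column is IC50 in nM, an already
transformed [0,1] binding value, or a binary label, declared by
``affinity_mode``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import AlphabetEncoding, load_blosum62_encoding
from .evaluation import binder_threshold_transformed, transform_affinity
from .pan import normalize_allele_name

AFFINITY_MODES = ("ic50_nM", "transformed", "binary")


@dataclass(frozen=True)
class BindingRecord:
    """One (allele, peptide, measured value) triple."""

    allele: str
    peptide: str
    value: float


@dataclass
class BindingDataset:
    """A validated collection of binding records with one affinity mode."""

    records: list
    affinity_mode: str = "ic50_nM"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.affinity_mode not in AFFINITY_MODES:
            raise ValueError(f"affinity_mode must be one of {AFFINITY_MODES}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alleles(self) -> list:
        return [r.allele for r in self.records]

    @property
    def peptides(self) -> list:
        return [r.peptide for r in self.records]

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    def targets(self) -> np.ndarray:
        """Regression targets on the transformed [0,1] scale."""
        v = self.values
        if self.affinity_mode == "ic50_nM":
            return transform_affinity(v)
        return v

    def labels(self, threshold: float = 500.0) -> np.ndarray:
        """Boolean binder labels at the given IC50 threshold (strict <)."""
        v = self.values
        if self.affinity_mode == "ic50_nM":
            return v < threshold
        if self.affinity_mode == "transformed":
            return v > binder_threshold_transformed(threshold)
        return v > 0.5

    def subset(self, idx) -> "BindingDataset":
        return BindingDataset(
            records=[self.records[i] for i in idx],
            affinity_mode=self.affinity_mode,
            provenance=dict(self.provenance, subset=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"allele": self.alleles, "peptide": self.peptides, "value": self.values}
        )


def make_dataset(alleles, peptides, values, affinity_mode="ic50_nM", provenance=None) -> BindingDataset:
    records = [
        BindingRecord(normalize_allele_name(a), str(p).upper(), float(v))
        for a, p, v in zip(alleles, peptides, values)
    ]
    return BindingDataset(records=records, affinity_mode=affinity_mode, provenance=provenance or {})


def _looks_like_header(fields) -> bool:
    if len(fields) < 3:
        return True
    try:
        float(fields[2])
        return False
    except ValueError:
        return True


def read_binding_tsv(
    path: str | Path,
    affinity_mode: str = "ic50_nM",
    residue_policy: str = "strict",
    enc: AlphabetEncoding | None = None,
) -> BindingDataset:
    """Read and validate a binding TSV (columns: allele, peptide, value).

    Header presence is auto-detected from whether the third field of the
    first data line parses as a number.  Peptides with residues outside the
    standard alphabet are fatal under the default ``strict`` policy and
    dropped with a warning under ``skip``.  Duplicate (allele, peptide)
    pairs keep the first record (a loud warning if the values conflict).
    Extra columns are ignored.
    """
    if enc is None:
        enc = load_blosum62_encoding()
    if residue_policy not in ("strict", "skip"):
        raise ValueError("residue_policy must be 'strict' or 'skip'")
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    data = []  # (line_no, fields)
    for ln_no, ln in enumerate(raw_lines, start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        data.append((ln_no, ln.split("\t") if "\t" in ln else ln.split()))
    if not data:
        raise ValueError(f"empty binding file: {path}")
    if _looks_like_header(data[0][1]):
        data = data[1:]
    if not data:
        raise ValueError(f"binding file has a header but no records: {path}")
    records = []
    seen: dict[tuple, float] = {}
    n_skipped = 0
    for ln_no, fields in data:
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln_no}: expected at least 3 columns, got {len(fields)}")
        allele = normalize_allele_name(fields[0])
        peptide = fields[1].strip().upper()
        try:
            value = float(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln_no}: unparseable value {fields[2]!r}") from exc
        bad = [i + 1 for i, ch in enumerate(peptide) if ch not in enc.index]
        if not peptide or bad:
            msg = f"{path}:{ln_no}: peptide {peptide!r} has non-standard residue at position(s) {bad}"
            if residue_policy == "strict":
                raise ValueError(msg)
            warnings.warn(msg + "; record skipped")
            n_skipped += 1
            continue
        if affinity_mode == "ic50_nM" and value <= 0:
            raise ValueError(f"{path}:{ln_no}: IC50 must be positive, got {value}")
        if affinity_mode == "transformed" and not (0.0 <= value <= 1.0):
            warnings.warn(f"{path}:{ln_no}: transformed value {value} outside [0,1]; kept")
        key = (allele, peptide)
        if key in seen:
            if seen[key] != value:
                warnings.warn(
                    f"{path}:{ln_no}: conflicting duplicate for {key}: {seen[key]} vs {value}; keeping first",
                    stacklevel=2,
                )
            else:
                warnings.warn(f"{path}:{ln_no}: duplicate record for {key}; keeping first")
            continue
        seen[key] = value
        records.append(BindingRecord(allele, peptide, value))
    if not records:
        raise ValueError(f"no usable records in {path}")
    provenance = {
        "path": str(path),
        "residue_policy": residue_policy,
        "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        "n_skipped": n_skipped,
    }
    return BindingDataset(records=records, affinity_mode=affinity_mode, provenance=provenance)


def write_binding_tsv(dataset: BindingDataset, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("allele\tpeptide\tvalue\n")
        for r in dataset.records:
            fh.write(f"{r.allele}\t{r.peptide}\t{r.value:.10g}\n")


def write_gram_tsv(gram, path: str | Path, header_comment: str | None = None) -> None:
    """Labeled square kernel matrix as TSV (header row/column of item ids)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("item\t" + "\t".join(str(i) for i in gram.items) + "\n")
        for item, row in zip(gram.items, gram.values):
            fh.write(str(item) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    """Read a tidy TSV (e.g. a prediction table) skipping ``#`` comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_fold_assignment(path: str | Path) -> dict:
    """TSV (allele, peptide, fold) -> mapping (allele, peptide) -> fold id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"allele", "peptide", "fold"}.issubset(df.columns):
        raise ValueError("fold-assignment file needs columns allele, peptide, fold")
    return {
        (normalize_allele_name(a), str(p).upper()): f
        for a, p, f in zip(df["allele"], df["peptide"], df["fold"])
    }
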