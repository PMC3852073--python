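"""Epsilon-SVR on precomputed string-kernel Gram matrices.

Models are scikit-learn style estimators: :class:`StringKernelSVR` predicts
transformed binding affinity from peptide sequences under one of the SRBF /
GS / MHC2SK kernels, and :class:`PanKernelSVR` predicts from (allele,
peptide) pairs under the MHC2SKpan product kernel.  Both delegate the dual
problem to libsvm (``sklearn.svm.SVR`` with a precomputed kernel) and keep
the dual solution bound to its training items so prediction can rebuild the
rectangular test-versus-support kernel on the fly.

Model selection follows the benchmark protocols of the field: grid search
over kernel hyperparameters scored by mean per-allele AUC (or PCC) under a
cross-validation plan, with k-fold-by-peptide, leave-one-allele-out and
fixed-partition schemes.  The SVR regularisation C and tube width epsilon
are not part of the grid; they default to the libsvm defaults (C=1,
epsilon=0.1) and are exposed as configuration.

Per-length Gram stacks make the grid cheap: the MHC2SK Gram for every
minimum-length cutoff L' is a suffix sum over fixed-length SRBF layers, so
one stack per sigma_c serves the whole (sigma_c, L') grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .encoding import AlphabetEncoding, encode_peptides, load_blosum62_encoding
from .evaluation import auc as auc_metric
from .evaluation import pcc as pcc_metric
from .io import BindingDataset
from .kernels import (
    GramMatrix,
    KernelParams,
    cosine_normalize,
    gram_matrix,
    rect_kernel_matrix,
    self_kernel_values,
    srbf_gram_stack,
)
from .pan import (
    PseudosequenceSet,
    allele_kernel_matrix,
    normalize_allele_name,
    pan_gram,
    pan_rect_matrix,
    pan_self_values,
)

DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1
SOLVER_TOL = 1e-3  # libsvm stopping criterion, recorded in model provenance

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# dual fit on a precomputed matrix
# ---------------------------------------------------------------------------

def _fit_dual(K: np.ndarray, y: np.ndarray, C: float, epsilon: float, tol: float):
    """Fit epsilon-SVR on a precomputed Gram matrix.

    Returns (alpha, bias, support_idx) with alpha indexed over the support
    vectors only.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("Gram matrix contains NaN or infinite entries")
    if K.shape[0] != K.shape[1] or np.max(np.abs(K - K.T)) > 1e-8:
        raise ValueError("precomputed Gram matrix must be square and symmetric")
    if not np.all(np.isfinite(y)) or len(y) != K.shape[0]:
        raise ValueError("targets must be finite and match the Gram matrix")
    svr = SVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol)
    svr.fit(K, y)
    return svr.dual_coef_[0].copy(), float(svr.intercept_[0]), svr.support_.copy()


@dataclass
class TrainedModel:
    """An SVR dual solution bound to its training items and kernel settings.

    ``support_items`` are peptide strings (allele-specific kernels) or
    (allele, peptide) string pairs (pan kernel).  Prediction computes
    f(z) = sum_i alpha_i K(item_i, z) + b with the recorded kernel, params
    and normalize flag.
    """

    kernel_name: str
    params: KernelParams
    support_items: list
    dual_coefs: np.ndarray
    bias: float
    normalize: bool = False
    svr_C: float = DEFAULT_C
    svr_epsilon: float = DEFAULT_EPSILON
    solver_tol: float = SOLVER_TOL
    pseudosequences: dict | None = None  # allele -> pseudoseq string (pan only)

    def __post_init__(self):
        if len(self.dual_coefs) != len(self.support_items):
            raise ValueError("one dual coefficient per support item required")

    def predict(self, items, enc: AlphabetEncoding | None = None) -> np.ndarray:
        """Predict for peptides (or (allele, peptide) pairs for the pan kernel)."""
        if enc is None:
            enc = load_blosum62_encoding()
        items = list(items)
        if not items:
            return np.zeros(0)
        if len(self.support_items) == 0:
            return np.full(len(items), self.bias)
        if self.kernel_name == "mhc2skpan":
            coll = _pseudoseq_collection(self.pseudosequences, enc)
            missing = sorted({normalize_allele_name(a) for a, _ in items} - set(coll.names()))
            if missing:
                raise ValueError(f"no pseudosequence for test allele(s): {missing}")
            K = pan_rect_matrix(items, self.support_items, coll, self.params, enc)
            if self.normalize:
                d_test = pan_self_values(items, coll, self.params, enc)
                d_sup = pan_self_values(self.support_items, coll, self.params, enc)
                K = K / np.sqrt(np.outer(d_test, d_sup))
        else:
            test_peps = encode_peptides(items, enc)
            sup_peps = encode_peptides(self.support_items, enc)
            K = rect_kernel_matrix(test_peps, sup_peps, self.kernel_name, self.params)
            if self.normalize:
                d_test = self_kernel_values(test_peps, self.kernel_name, self.params)
                d_sup = self_kernel_values(sup_peps, self.kernel_name, self.params)
                K = K / np.sqrt(np.outer(d_test, d_sup))
        return K @ self.dual_coefs + self.bias

    # -- serialization (single self-describing text archive) ---------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "kernel_name": self.kernel_name,
            "params": asdict(self.params),
            "support_items": [list(it) if isinstance(it, tuple) else it for it in self.support_items],
            "dual_coefs": [float(v) for v in self.dual_coefs],
            "bias": self.bias,
            "normalize": self.normalize,
            "svr_C": self.svr_C,
            "svr_epsilon": self.svr_epsilon,
            "solver_tol": self.solver_tol,
            "pseudosequences": self.pseudosequences,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        items = [tuple(it) if isinstance(it, list) else it for it in d["support_items"]]
        return cls(
            kernel_name=d["kernel_name"],
            params=KernelParams(**d["params"]),
            support_items=items,
            dual_coefs=np.array(d["dual_coefs"], dtype=float),
            bias=float(d["bias"]),
            normalize=bool(d["normalize"]),
            svr_C=float(d["svr_C"]),
            svr_epsilon=float(d["svr_epsilon"]),
            solver_tol=float(d["solver_tol"]),
            pseudosequences=d.get("pseudosequences"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pseudoseq_collection(mapping: dict, enc: AlphabetEncoding) -> PseudosequenceSet:
    coll = PseudosequenceSet()
    for name, seq in mapping.items():
        coll.add(name, seq, enc)
    return coll


def train_svr(
    gram: GramMatrix,
    targets,
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = SOLVER_TOL,
    pseudosequences: dict | None = None,
) -> TrainedModel:
    """Train epsilon-SVR on a precomputed :class:`GramMatrix`.

    ``gram.items`` identify the training items; for the pan kernel they are
    ``allele/peptide`` strings and ``pseudosequences`` must be supplied so
    the model can predict later.
    """
    alpha, bias, support = _fit_dual(gram.values, np.asarray(targets, dtype=float), C, epsilon, tol)
    if gram.kernel_name == "mhc2skpan":
        items = [tuple(str(gram.items[i]).split("/", 1)) for i in support]
        if pseudosequences is None:
            raise ValueError("pan models require a pseudosequence mapping")
    else:
        items = [gram.items[i] for i in support]
    return TrainedModel(
        kernel_name=gram.kernel_name,
        params=gram.params,
        support_items=items,
        dual_coefs=alpha,
        bias=bias,
        normalize=gram.normalized,
        svr_C=C,
        svr_epsilon=epsilon,
        solver_tol=tol,
        pseudosequences=pseudosequences,
    )


def predict(model: TrainedModel, test_items, enc: AlphabetEncoding | None = None) -> np.ndarray:
    """Functional form of :meth:`TrainedModel.predict`."""
    return model.predict(test_items, enc)


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class StringKernelSVR(BaseEstimator, RegressorMixin):
    """Peptide-sequence SVR under the SRBF, GS or MHC2SK string kernel.

    Parameters mirror :class:`~mhc2sk.kernels.KernelParams`; only the ones
    relevant to the chosen kernel matter.  ``X`` is a sequence of peptide
    strings; ``y`` the transformed binding affinities.

    Examples
    --------
    >>> model = StringKernelSVR(kernel="mhc2sk", sigma_c=5.0, l_min=9)
    >>> model.fit(["ACDEFGHIKLM", "MLKIHGFEDCA"], [0.8, 0.2])  # doctest: +ELLIPSIS
    StringKernelSVR(...)
    """

    def __init__(
        self,
        kernel: str = "mhc2sk",
        sigma_c: float = 5.0,
        l_min: int = 9,
        srbf_length: int = 9,
        L: int = 10,
        sigma_p: float = 1.0,
        C: float = DEFAULT_C,
        epsilon: float = DEFAULT_EPSILON,
        normalize: bool = False,
        tol: float = SOLVER_TOL,
    ):
        self.kernel = kernel
        self.sigma_c = sigma_c
        self.l_min = l_min
        self.srbf_length = srbf_length
        self.L = L
        self.sigma_p = sigma_p
        self.C = C
        self.epsilon = epsilon
        self.normalize = normalize
        self.tol = tol

    def _kernel_params(self) -> KernelParams:
        return KernelParams(
            sigma_c=self.sigma_c,
            sigma_p=self.sigma_p,
            L=self.L,
            l_min=self.l_min,
            srbf_length=self.srbf_length,
        )

    def fit(self, X, y):
        peptides = [str(p) for p in X]
        y = np.asarray(y, dtype=float)
        if len(peptides) != len(y):
            raise ValueError("X and y must have the same length")
        gram = gram_matrix(peptides, self.kernel, self._kernel_params(), normalize=self.normalize)
        self.model_ = train_svr(gram, y, C=self.C, epsilon=self.epsilon, tol=self.tol)
        self.support_items_ = list(self.model_.support_items)
        self.dual_coef_ = self.model_.dual_coefs
        self.intercept_ = self.model_.bias
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict([str(p) for p in X])


class PanKernelSVR(BaseEstimator, RegressorMixin):
    """(allele, peptide) SVR under the MHC2SKpan product kernel.

    ``pseudosequences`` maps allele names to their fixed-length
    pseudosequences (a dict or :class:`~mhc2sk.pan.PseudosequenceSet`); all
    training and test alleles must be present.  ``X`` is an iterable of
    (allele, peptide) pairs (e.g. an (n, 2) object array).
    """

    def __init__(
        self,
        pseudosequences=None,
        sigma_a: float = 6.5,
        sigma_c: float = 5.0,
        l_min: int = 9,
        C: float = DEFAULT_C,
        epsilon: float = DEFAULT_EPSILON,
        normalize: bool = False,
        tol: float = SOLVER_TOL,
    ):
        self.pseudosequences = pseudosequences
        self.sigma_a = sigma_a
        self.sigma_c = sigma_c
        self.l_min = l_min
        self.C = C
        self.epsilon = epsilon
        self.normalize = normalize
        self.tol = tol

    def _kernel_params(self) -> KernelParams:
        return KernelParams(sigma_c=self.sigma_c, l_min=self.l_min, sigma_a=self.sigma_a)

    def _pseudo_mapping(self) -> dict:
        ps = self.pseudosequences
        if ps is None:
            raise ValueError("PanKernelSVR requires a pseudosequence mapping")
        if isinstance(ps, PseudosequenceSet):
            return {e.allele_name: e.pseudoseq for e in ps.entries.values()}
        return dict(ps)

    def fit(self, X, y):
        items = [(normalize_allele_name(a), str(p).upper()) for a, p in X]
        y = np.asarray(y, dtype=float)
        if len(items) != len(y):
            raise ValueError("X and y must have the same length")
        enc = load_blosum62_encoding()
        mapping = self._pseudo_mapping()
        coll = _pseudoseq_collection(mapping, enc)
        gram = pan_gram(items, coll, self._kernel_params(), normalize=self.normalize, enc=enc)
        self.model_ = train_svr(
            gram, y, C=self.C, epsilon=self.epsilon, tol=self.tol, pseudosequences=mapping
        )
        self.support_items_ = list(self.model_.support_items)
        self.dual_coef_ = self.model_.dual_coefs
        self.intercept_ = self.model_.bias
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        items = [(normalize_allele_name(a), str(p).upper()) for a, p in X]
        return self.model_.predict(items)


# ---------------------------------------------------------------------------
# cross-validation plans
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """How to partition a dataset for cross-validation.

    scheme is one of ``kfold_by_peptide`` (records shuffled by ``seed`` and
    split into ``n_folds``), ``leave_one_allele_out`` (one fold per distinct
    allele) or ``fixed_partition`` (folds read from ``fold_assignment``, a
    mapping (allele, peptide) -> fold id).
    """

    scheme: str = "kfold_by_peptide"
    n_folds: int = 5
    fold_assignment: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("kfold_by_peptide", "leave_one_allele_out", "fixed_partition"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold_by_peptide" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.scheme == "fixed_partition" and not self.fold_assignment:
            raise ValueError("fixed_partition requires a fold_assignment mapping")

    def folds(self, dataset: BindingDataset):
        """Yield (fold_id, train_idx, test_idx) covering every record once."""
        n = len(dataset)
        idx = np.arange(n)
        out = []
        if self.scheme == "kfold_by_peptide":
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            for f, test in enumerate(np.array_split(perm, self.n_folds)):
                test = np.sort(test)
                train = np.setdiff1d(idx, test)
                out.append((f, train, test))
        elif self.scheme == "leave_one_allele_out":
            alleles = np.array(dataset.alleles)
            for f, allele in enumerate(sorted(set(alleles))):
                test = idx[alleles == allele]
                train = idx[alleles != allele]
                out.append((allele, train, test))
        else:
            keys = [(r.allele, r.peptide) for r in dataset.records]
            missing = [k for k in keys if k not in self.fold_assignment]
            if missing:
                raise ValueError(f"{len(missing)} record(s) missing from the fold assignment, e.g. {missing[0]}")
            fold_ids = np.array([self.fold_assignment[k] for k in keys])
            for f in sorted(set(fold_ids.tolist())):
                test = idx[fold_ids == f]
                train = idx[fold_ids != f]
                out.append((f, train, test))
        for f, train, test in out:
            if len(train) == 0:
                raise ValueError(f"fold {f!r} has no training data")
        return out


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _float_range(lo: float, hi: float, step: float) -> list:
    return [round(lo + i * step, 10) for i in range(int(round((hi - lo) / step)) + 1)]


@dataclass
class GridSpec:
    """Hyperparameter grids (defaults discretise the search ranges
    sigma_c in (0,5], sigma_p and sigma_a in (0,15] at step 0.5, L' in
    [1,9], L in [1,20])."""

    sigma_c_values: list = field(default_factory=lambda: _float_range(0.5, 5.0, 0.5))
    sigma_p_values: list = field(default_factory=lambda: _float_range(0.5, 15.0, 0.5))
    sigma_a_values: list = field(default_factory=lambda: _float_range(0.5, 15.0, 0.5))
    L_values: list = field(default_factory=lambda: list(range(1, 21)))
    l_min_values: list = field(default_factory=lambda: list(range(1, 10)))

    def __post_init__(self):
        checks = [
            ("sigma_c_values", self.sigma_c_values, 0.0, 5.0),
            ("sigma_p_values", self.sigma_p_values, 0.0, 15.0),
            ("sigma_a_values", self.sigma_a_values, 0.0, 15.0),
            ("L_values", self.L_values, 1, 20),
            ("l_min_values", self.l_min_values, 1, 9),
        ]
        for name, vals, lo, hi in checks:
            if not list(vals):
                raise ValueError(f"{name} must be non-empty")
            if min(vals) <= lo - 1e-12 and name.startswith("sigma"):
                raise ValueError(f"{name} must be strictly positive")
            if min(vals) < lo or max(vals) > hi:
                raise ValueError(f"{name} must lie within [{lo}, {hi}]")


def _objective_fn(objective: str):
    if objective.upper() == "AUC":
        return lambda pred, target, label: auc_metric(pred, label)
    if objective.upper() == "PCC":
        return lambda pred, target, label: pcc_metric(pred, target)
    raise ValueError("objective must be 'AUC' or 'PCC'")


class _KernelGridEngine:
    """Precomputed Gram layers over one dataset for a whole hyperparameter grid.

    Kernel values carry no label information, so they can be computed once
    over the full dataset and sliced per CV fold without leakage; this is
    what makes nested model selection affordable.  For the substring kernels
    each (sigma_c, length-cutoff) Gram is a suffix (MHC2SK) or single layer
    (SRBF) of one per-length stack per sigma_c; GS needs one stack per
    (sigma_c, sigma_p), with the L grid free via prefix sums; the pan
    kernel multiplies a cached peptide layer by a per-sigma_a allele factor.
    Memory is one N x N matrix per retained grid layer.
    """

    def __init__(self, dataset, kernel_name, grid, pseudoseqs, normalize, enc):
        self.name = kernel_name.lower()
        self.grid = grid
        self.normalize = normalize
        self.targets = dataset.targets()
        self.labels = dataset.labels()
        self.alleles = dataset.alleles
        n = len(dataset)
        peptides = encode_peptides(dataset.peptides, enc)
        l_max = max(len(p) for p in peptides)
        self._layers = {}  # (sigma_c[, sigma_p], cutoff) -> N x N peptide Gram
        self._allele_factor = {}  # sigma_a -> N x N
        if self.name == "mhc2skpan":
            if pseudoseqs is None:
                raise ValueError("pan grid search requires pseudosequences")
            uniq = sorted({normalize_allele_name(a) for a in self.alleles})
            self._uniq_entries = [pseudoseqs[a] for a in uniq]
            self._amap = np.array([uniq.index(normalize_allele_name(a)) for a in self.alleles])
        if self.name == "gs":
            from .kernels import _grouped_pair_values, _square_from_pairs

            iu = np.triu_indices(n)
            L_top = max(grid.L_values)
            for sigma_c in grid.sigma_c_values:
                T = enc.exp_table(sigma_c)
                for sigma_p in grid.sigma_p_values:
                    vals = _grouped_pair_values(
                        peptides, peptides, iu[0], iu[1], T, 1, L_top, sigma_p=sigma_p, stack_l=L_top
                    )
                    prefix = np.cumsum(vals, axis=0)
                    for L in grid.L_values:
                        self._layers[(sigma_c, sigma_p, L)] = _square_from_pairs(n, prefix[L - 1])
        else:
            for sigma_c in grid.sigma_c_values:
                stack = srbf_gram_stack(peptides, sigma_c, l_max)
                if self.name == "srbf":
                    for l in grid.l_min_values:
                        self._layers[(sigma_c, l)] = stack[l - 1]
                else:
                    suffix = np.flip(np.cumsum(np.flip(stack, 0), 0), 0)
                    for l_min in grid.l_min_values:
                        self._layers[(sigma_c, l_min)] = suffix[l_min - 1]
                del stack

    def points(self):
        """Grid points in lexicographic tie-break order (sigma_c, then the
        length cutoff, then sigma_a; for GS sigma_c, sigma_p, L)."""
        g = self.grid
        if self.name == "gs":
            return [
                KernelParams(sigma_c=sc, sigma_p=sp, L=L)
                for sc in g.sigma_c_values for sp in g.sigma_p_values for L in g.L_values
            ]
        if self.name == "srbf":
            return [
                KernelParams(sigma_c=sc, srbf_length=l)
                for sc in g.sigma_c_values for l in g.l_min_values
            ]
        if self.name == "mhc2sk":
            return [
                KernelParams(sigma_c=sc, l_min=l)
                for sc in g.sigma_c_values for l in g.l_min_values
            ]
        return [
            KernelParams(sigma_c=sc, l_min=l, sigma_a=sa)
            for sc in g.sigma_c_values for l in g.l_min_values for sa in g.sigma_a_values
        ]

    def gram(self, params: KernelParams) -> np.ndarray | None:
        """Full-dataset Gram at one grid point; None for degenerate layers
        (an SRBF length exceeding every peptide)."""
        if self.name == "gs":
            K = self._layers[(params.sigma_c, params.sigma_p, params.L)]
        elif self.name == "srbf":
            K = self._layers[(params.sigma_c, params.srbf_length)]
        else:
            K = self._layers[(params.sigma_c, params.l_min)]
        if self.name == "mhc2skpan":
            if params.sigma_a not in self._allele_factor:
                Ka_u = allele_kernel_matrix(self._uniq_entries, self._uniq_entries, params.sigma_a)
                self._allele_factor[params.sigma_a] = Ka_u[np.ix_(self._amap, self._amap)]
            K = self._allele_factor[params.sigma_a] * K
        if np.any(np.diag(K) <= 0):
            return None
        return cosine_normalize(K) if self.normalize else K

    def score(self, K, folds, objective_fn, C, epsilon, allele_subset=None) -> float:
        """Mean per-allele objective of CV predictions (pooled across folds).

        ``folds`` hold global index arrays; ``allele_subset`` restricts the
        per-allele averaging to the records appearing in the folds.
        """
        test_all = np.concatenate([test for _, _, test in folds])
        pred = np.full(len(self.targets), np.nan)
        for _, train, test in folds:
            alpha, bias, support = _fit_dual(
                K[np.ix_(train, train)], self.targets[train], C, epsilon, SOLVER_TOL
            )
            pred[test] = K[np.ix_(test, train[support])] @ alpha + bias
        alleles = np.array(self.alleles)
        per_allele = []
        for allele in sorted(set(alleles[test_all])):
            m = np.flatnonzero((alleles == allele) & ~np.isnan(pred))
            if len(m) == 0:
                continue
            per_allele.append(objective_fn(pred[m], self.targets[m], self.labels[m]))
        vals = np.asarray(per_allele, dtype=float)
        good = vals[~np.isnan(vals)]
        return float(good.mean()) if len(good) else float("nan")

    def search(self, folds, objective_fn, C, epsilon):
        """Best grid point under the given folds; returns (params, rows)."""
        best = None
        rows = []
        for params in self.points():
            K = self.gram(params)
            score = float("nan") if K is None else self.score(K, folds, objective_fn, C, epsilon)
            row = {"sigma_c": params.sigma_c, "score": score}
            if self.name == "gs":
                row.update(sigma_p=params.sigma_p, L=params.L)
            elif self.name == "srbf":
                row.update(l=params.srbf_length)
            else:
                row.update(l_min=params.l_min)
                if self.name == "mhc2skpan":
                    row.update(sigma_a=params.sigma_a)
            rows.append(row)
            if not np.isnan(score) and (best is None or score > best[0]):
                best = (score, params)
        if best is None:
            raise ValueError(
                "all grid points were degenerate (no fold produced a defined objective); "
                "check class balance within folds"
            )
        return best[1], rows


def grid_search(
    dataset: BindingDataset,
    grid: GridSpec,
    plan: CVPlan,
    objective: str = "AUC",
    kernel_name: str = "mhc2sk",
    pseudoseqs: PseudosequenceSet | None = None,
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    normalize: bool = False,
    enc: AlphabetEncoding | None = None,
):
    """Exhaustive grid search scored by cross-validated mean per-allele objective.

    Every grid point is evaluated by CV under ``plan`` (predictions pooled
    per allele across folds); the best point wins, ties broken by first
    position in lexicographic grid order (sigma_c, then the length cutoff,
    then sigma_a; for GS sigma_c, sigma_p, L).  Returns
    ``(KernelParams, score_table)``.
    """
    if enc is None:
        enc = load_blosum62_encoding()
    objective_fn = _objective_fn(objective)
    labels = dataset.labels()
    if objective.upper() == "AUC" and (labels.all() or (~labels).all()):
        raise ValueError("AUC objective requires both binder classes in the dataset")
    engine = _KernelGridEngine(dataset, kernel_name, grid, pseudoseqs, normalize, enc)
    best, rows = engine.search(plan.folds(dataset), objective_fn, C, epsilon)
    return best, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def _full_gram(dataset, kernel_name, params, pseudoseqs, normalize, enc) -> np.ndarray:
    if kernel_name == "mhc2skpan":
        items = list(zip(dataset.alleles, dataset.peptides))
        return pan_gram(items, pseudoseqs, params, normalize=normalize, enc=enc).values
    return gram_matrix(dataset.peptides, kernel_name, params, normalize=normalize, enc=enc).values


def run_cv(
    dataset: BindingDataset,
    plan: CVPlan,
    kernel_name: str = "mhc2sk",
    params: KernelParams | None = None,
    grid: GridSpec | None = None,
    pseudoseqs: PseudosequenceSet | None = None,
    objective: str = "AUC",
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    normalize: bool = False,
    inner_folds: int = 4,
    enc: AlphabetEncoding | None = None,
) -> pd.DataFrame:
    """Cross-validate and return a tidy prediction table.

    Exactly one of ``params`` (fixed hyperparameters) or ``grid`` (inner
    model selection) must be given.  With a grid, each outer training fold
    runs an inner ``inner_folds``-fold-by-peptide grid search scored by
    ``objective`` and the winning parameters build that fold's model.
    Columns of the result: allele, peptide, observed (the dataset's raw
    value), predicted, fold.
    """
    if (params is None) == (grid is None):
        raise ValueError("provide exactly one of params= or grid=")
    if enc is None:
        enc = load_blosum62_encoding()
    name = kernel_name.lower()
    if name == "mhc2skpan" and pseudoseqs is None:
        raise ValueError("pan cross-validation requires pseudosequences")
    folds = plan.folds(dataset)
    targets = dataset.targets()
    rows = []
    engine = None
    K_full = None
    if params is not None:
        K_full = _full_gram(dataset, name, params, pseudoseqs, normalize, enc)
    else:
        engine = _KernelGridEngine(dataset, name, grid, pseudoseqs, normalize, enc)
        objective_fn = _objective_fn(objective)
    for fold_id, train, test in folds:
        if engine is not None:
            inner_folds_global = _inner_folds(dataset, plan, train, inner_folds)
            fold_params, _ = engine.search(inner_folds_global, objective_fn, C, epsilon)
            K = engine.gram(fold_params)
        else:
            K = K_full
        alpha, bias, support = _fit_dual(K[np.ix_(train, train)], targets[train], C, epsilon, SOLVER_TOL)
        pred = K[np.ix_(test, train[support])] @ alpha + bias
        for i, p in zip(test, pred):
            r = dataset.records[i]
            rows.append(
                {"allele": r.allele, "peptide": r.peptide, "observed": r.value,
                 "predicted": float(p), "fold": fold_id}
            )
    return pd.DataFrame(rows)


def sigma_a_sensitivity_curve(
    dataset: BindingDataset,
    pseudoseqs: PseudosequenceSet,
    held_out_allele: str,
    sigma_c: float = 5.0,
    l_min: int = 1,
    sigma_a_values=None,
    C: float = DEFAULT_C,
    epsilon: float = DEFAULT_EPSILON,
    enc: AlphabetEncoding | None = None,
) -> pd.DataFrame:
    """AUC on one held-out allele as the allele bandwidth sigma_a sweeps.

    The model is trained on every other allele's records for each sigma_a
    (default sweep 0.5..15, step 0.5).  A small sigma_a shares binding data
    only between near-identical pseudosequences; a large one pools all
    alleles — the curve shows how far pooling helps the target allele.
    Returns a tidy frame (sigma_a, auc, n_train, n_test).
    """
    if enc is None:
        enc = load_blosum62_encoding()
    if sigma_a_values is None:
        sigma_a_values = [0.5 * k for k in range(1, 31)]
    held = normalize_allele_name(held_out_allele)
    alleles = np.array([normalize_allele_name(a) for a in dataset.alleles])
    if held not in alleles:
        raise ValueError(f"allele {held_out_allele!r} not present in the dataset")
    test = np.flatnonzero(alleles == held)
    train = np.flatnonzero(alleles != held)
    peptides = encode_peptides(dataset.peptides, enc)
    stack = srbf_gram_stack(peptides, sigma_c, max(len(p) for p in peptides))
    Kp = stack[l_min - 1 :].sum(axis=0)
    uniq = sorted(set(alleles))
    amap = np.array([uniq.index(a) for a in alleles])
    entries = [pseudoseqs[a] for a in uniq]
    targets, labels = dataset.targets(), dataset.labels()
    rows = []
    for sigma_a in sigma_a_values:
        Ka = allele_kernel_matrix(entries, entries, sigma_a)[np.ix_(amap, amap)]
        K = Ka * Kp
        alpha, bias, support = _fit_dual(K[np.ix_(train, train)], targets[train], C, epsilon, SOLVER_TOL)
        pred = K[np.ix_(test, train[support])] @ alpha + bias
        rows.append({"sigma_a": sigma_a, "auc": auc_metric(pred, labels[test]),
                     "n_train": len(train), "n_test": len(test)})
    return pd.DataFrame(rows)


def _inner_folds(dataset, outer_plan: CVPlan, train: np.ndarray, inner_folds: int):
    """Inner model-selection folds over one outer training set, as global indices.

    The inner scheme mirrors the outer one: leave-one-allele-out outer CV
    selects parameters by leave-one-allele-out over the training alleles
    (novel-allele generalization is what is being tuned for); any other
    scheme uses ``inner_folds``-fold CV by peptide.
    """
    if outer_plan.scheme == "leave_one_allele_out":
        inner_plan = CVPlan(scheme="leave_one_allele_out", seed=outer_plan.seed)
    else:
        inner_plan = CVPlan(scheme="kfold_by_peptide", n_folds=inner_folds, seed=outer_plan.seed)
    sub = dataset.subset(train)
    return [(f, train[tr], train[te]) for f, tr, te in inner_plan.folds(sub)]
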