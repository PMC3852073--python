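"""Affinity transforms, binder labeling, per-allele metrics, and the sign test.

Measured IC50 values (nM) are mapped to the regression target scale by
``1 - log(IC50) / log(50000)``, so 50000 nM -> 0 and 1 nM -> 1; a peptide
with IC50 strictly below 500 nM counts as a binder.  Performance is
summarised per allele by ROC AUC (binder vs non-binder, Mann-Whitney with
midrank tie handling) and the Pearson correlation between predicted and
transformed observed affinities; method comparisons use the exact one-tailed
per-allele sign (binomial) test with ties excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

IC50_MAX = 50_000.0
BINDER_THRESHOLD_NM = 500.0


def transform_affinity(ic50_nM, clamp: bool = True):
    """``1 - log(IC50)/log(50000)``, elementwise; IC50 must be positive.

    By default values are clamped to [0, 1] (IC50 outside [1, 50000] nM);
    pass ``clamp=False`` for the raw transform.
    """
    x = np.asarray(ic50_nM, dtype=float)
    if np.any(x <= 0):
        raise ValueError("IC50 values must be strictly positive")
    t = 1.0 - np.log(x) / np.log(IC50_MAX)
    if clamp:
        t = np.clip(t, 0.0, 1.0)
    return float(t) if np.isscalar(ic50_nM) else t


def inverse_transform_affinity(t):
    """IC50 (nM) corresponding to a transformed binding value."""
    t = np.asarray(t, dtype=float)
    out = np.power(IC50_MAX, 1.0 - t)
    return float(out) if out.ndim == 0 else out


def label_binder(ic50_nM, threshold: float = BINDER_THRESHOLD_NM):
    """True iff IC50 is strictly less than the threshold (default 500 nM)."""
    x = np.asarray(ic50_nM, dtype=float)
    if np.any(x <= 0):
        raise ValueError("IC50 values must be strictly positive")
    out = x < threshold
    return bool(out) if np.isscalar(ic50_nM) else out


#: transformed-scale equivalent of the 500 nM binder threshold
def binder_threshold_transformed(threshold: float = BINDER_THRESHOLD_NM) -> float:
    return transform_affinity(threshold)


def auc(scores, labels) -> float:
    """ROC AUC, Mann-Whitney formulation with midrank tie handling.

    Returns NaN (undefined marker) when only one class is present so that
    macro averaging can skip the allele rather than crash.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pcc(pred, obs) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pcc requires two equal-length vectors of size >= 2")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


@dataclass
class ComparisonResult:
    """Outcome of the per-allele sign test between two methods."""

    n_wins: int
    n_compared: int
    p_value: float


def binomial_compare(per_allele_metric_a, per_allele_metric_b) -> ComparisonResult:
    """Exact one-tailed sign test on per-allele metric wins of A over B.

    Ties are excluded; under H0 each non-tied allele is a fair coin, so
    p = sum_{i>=k} C(n, i) 0.5^n.  All-ties gives a NaN p-value.
    """
    a = np.asarray(per_allele_metric_a, dtype=float)
    b = np.asarray(per_allele_metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-allele metric vectors must have equal length")
    mask = a != b
    n = int(mask.sum())
    wins = int((a[mask] > b[mask]).sum())
    if n == 0:
        return ComparisonResult(0, 0, float("nan"))
    p = stats.binomtest(wins, n, 0.5, alternative="greater").pvalue
    return ComparisonResult(wins, n, float(p))


@dataclass
class EvaluationResult:
    """Per-allele AUC/PCC table plus unweighted macro averages."""

    per_allele: pd.DataFrame
    macro: dict


def evaluate_predictions(
    table: pd.DataFrame,
    affinity_mode: str = "ic50_nM",
    threshold: float = BINDER_THRESHOLD_NM,
    per_fold: bool = False,
) -> EvaluationResult:
    """Per-allele AUC and PCC from a tidy prediction table.

    ``table`` must have columns allele, observed, predicted (and fold when
    ``per_fold``).  ``observed`` is interpreted per ``affinity_mode``:
    IC50 in nM, an already transformed [0,1] value, or a binary label.
    Predictions from all folds for one allele are pooled by default;
    ``per_fold=True`` computes metrics per (allele, fold) and averages the
    folds within each allele instead.
    """
    required = {"allele", "observed", "predicted"}
    if not required.issubset(table.columns):
        raise ValueError(f"prediction table must have columns {sorted(required)}")
    mode = affinity_mode.lower()
    obs = np.asarray(table["observed"], dtype=float)
    if mode == "ic50_nm":
        target = transform_affinity(obs)
        labels = obs < threshold
    elif mode == "transformed":
        target = obs
        labels = obs > binder_threshold_transformed(threshold)
    elif mode == "binary":
        target = obs
        labels = obs > 0.5
    else:
        raise ValueError(f"unknown affinity_mode {affinity_mode!r}")
    work = table.copy()
    work["_target"] = target
    work["_label"] = labels

    def _metrics(g: pd.DataFrame) -> tuple[float, float]:
        a = auc(g["predicted"], g["_label"])
        p = pcc(g["predicted"], g["_target"]) if len(g) >= 2 else float("nan")
        return a, p

    rows = []
    for allele, g in work.groupby("allele", sort=True):
        if per_fold:
            per = [_metrics(gf) for _, gf in g.groupby("fold", sort=True)]
            aucs = [x[0] for x in per]
            pccs = [x[1] for x in per]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                a_val = float(np.nanmean(aucs)) if not np.all(np.isnan(aucs)) else float("nan")
                p_val = float(np.nanmean(pccs)) if not np.all(np.isnan(pccs)) else float("nan")
        else:
            a_val, p_val = _metrics(g)
        rows.append({"allele": allele, "n_peptides": len(g), "AUC": a_val, "PCC": p_val})
    per_allele = pd.DataFrame(rows)
    macro = {}
    for col in ("AUC", "PCC"):
        vals = per_allele[col].to_numpy()
        good = vals[~np.isnan(vals)]
        if len(good) < len(vals):
            warnings.warn(f"{len(vals) - len(good)} allele(s) had undefined {col}; skipped in macro average")
        macro[col] = float(good.mean()) if len(good) else float("nan")
    return EvaluationResult(per_allele=per_allele, macro=macro)
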