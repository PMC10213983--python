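"""Agreement metrics for 5-class sleep staging, computed from a confusion table.

All three headline metrics — overall accuracy, macro-averaged F1 and
Cohen's kappa — are exact functions of the 5x5 confusion table (rows = true
stage, columns = predicted stage), so they are computed from counts rather
than streamed.
"""

from __future__ import annotations

import numpy as np

from .signals import STAGES

__all__ = [
    "confusion_table",
    "overall_accuracy",
    "macro_f1",
    "cohens_kappa",
    "class_fractions",
    "DATASET_STAGE_COUNTS",
]

# Printed per-stage epoch counts of the four public cohorts (dataset
# metadata used for class-balance bookkeeping and synthetic defaults).
DATASET_STAGE_COUNTS = {
    "sleep-edf-78": {"W": 65951, "N1": 21522, "N2": 69132, "N3": 13039, "REM": 25835},
    "sleep-edf-20": {"W": 8183, "N1": 2909, "N2": 17509, "N3": 6006, "REM": 7701},
    "isruc-1": {"W": 18237, "N1": 11110, "N2": 27232, "N3": 18188, "REM": 12420},
    "isruc-3": {"W": 1647, "N1": 1188, "N2": 2660, "N3": 1939, "REM": 1155},
}


def class_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Per-class fraction of total epochs from a stage-count table."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: v / total for k, v in counts.items()}


def confusion_table(y_true, y_pred, n_classes: int = len(STAGES)) -> np.ndarray:
    """5x5 count table; rows index the true class, columns the prediction."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays differ in length")
    ct = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(ct, (y_true, y_pred), 1)
    return ct


def _check(ct: np.ndarray) -> np.ndarray:
    ct = np.asarray(ct)
    if ct.ndim != 2 or ct.shape[0] != ct.shape[1]:
        raise ValueError("confusion table must be square")
    if ct.sum() <= 0:
        raise ValueError("confusion table is empty")
    if (ct < 0).any():
        raise ValueError("confusion table has negative counts")
    return ct


def overall_accuracy(ct: np.ndarray) -> float:
    """ACC = sum_t TP_t / N  (trace over total)."""
    ct = _check(ct)
    return float(np.trace(ct) / ct.sum())


def macro_f1(ct: np.ndarray) -> float:
    """Unweighted mean per-class F1; a class with no true or predicted
    samples contributes F1 = 0."""
    ct = _check(ct)
    tp = np.diag(ct).astype(float)
    fp = ct.sum(axis=0) - tp
    fn = ct.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return float(f1.mean())


def cohens_kappa(ct: np.ndarray) -> float:
    """kappa = (ACC - p_e) / (1 - p_e) with p_e from the marginal products.

    Degenerate marginals (p_e = 1, e.g. a single-class table) return 0 with
    a warning: observed and chance agreement coincide, so no chance
    correction is identifiable.
    """
    import warnings

    ct = _check(ct)
    n = ct.sum()
    pe = float((ct.sum(axis=1) * ct.sum(axis=0)).sum() / (n * n))
    acc = overall_accuracy(ct)
    if abs(1.0 - pe) < 1e-12:
        warnings.warn("degenerate marginals: p_e = 1, kappa defined as 0")
        return 0.0
    return float((acc - pe) / (1.0 - pe))
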