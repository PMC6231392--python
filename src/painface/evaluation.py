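"""Hit Rate / False Acceptance Rate, ROC curves and per-GOP HR ranges.

HR is the true-positive rate for pain (true pain frames labelled pain);
FAR is the fraction of non-pain frames (neutral and other expressions
pooled) labelled pain.  The ROC sweeps the pain threshold over the
per-frame distances; AUC is trapezoidal.  The per-GOP HR range reports
the minimum and maximum window-level hit rate over consecutive windows
of ``gop`` frames, the form in which per-video accuracy is quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skmetrics

from .classifier import PAIN, ClassificationResult


class ROCError(ValueError):
    pass


@dataclass
class EvalReport:
    hr: float | None
    far: float
    hr_range: tuple[float, float] | None
    roc_points: np.ndarray | None
    auc: float | None
    gop: int = 15

    def to_dict(self) -> dict:
        return {
            "hr": self.hr,
            "far": self.far,
            "hr_range": list(self.hr_range) if self.hr_range else None,
            "auc": self.auc,
            "gop": self.gop,
        }


def _predicted_pain(results) -> np.ndarray:
    return np.array([
        (r.label if isinstance(r, ClassificationResult) else r) == PAIN for r in results
    ])


def _truth_pain(truth) -> np.ndarray:
    return np.array([t == PAIN if isinstance(t, str) else bool(t) for t in truth])


def compute_hr_far(results, truth) -> tuple[float | None, float]:
    """(hit rate, false acceptance rate); HR is None without pain truth."""
    pred = _predicted_pain(results)
    true = _truth_pain(truth)
    if len(pred) != len(true):
        raise ValueError("results and truth must be aligned")
    n_pain = int(true.sum())
    n_rest = len(true) - n_pain
    hr = float((pred & true).sum() / n_pain) if n_pain else None
    far = float((pred & ~true).sum() / n_rest) if n_rest else 0.0
    return hr, far


def roc_curve(diffs, truth):
    """ROC by sweeping the pain threshold over the frame distances.

    Returns (points, auc) with points an (m, 2) array of (far, hr)
    sorted by far and auc the trapezoidal area.
    """
    d = np.asarray(diffs, float)
    true = _truth_pain(truth)
    if true.all() or not true.any():
        raise ROCError("ROC needs at least one pain and one non-pain frame")
    far, hr, _ = _skmetrics.roc_curve(true.astype(int), d)
    auc = float(_skmetrics.auc(far, hr))
    return np.column_stack([far, hr]), auc


def hr_range_by_gop(results, truth, gop: int = 15):
    """(min, max) window-level hit rate over consecutive gop-frame windows.

    Only windows containing at least one true pain frame contribute.
    Returns None when no window qualifies.
    """
    if gop < 1:
        raise ValueError("gop must be >= 1")
    pred = _predicted_pain(results)
    true = _truth_pain(truth)
    rates = []
    for start in range(0, len(true), gop):
        t = true[start : start + gop]
        p = pred[start : start + gop]
        if t.any():
            rates.append(float((p & t).sum() / t.sum()))
    if not rates:
        return None
    return (min(rates), max(rates))


def evaluate(results, truth, diffs=None, gop: int = 15) -> EvalReport:
    """Full report: HR, FAR, per-GOP HR range, and ROC/AUC when possible."""
    hr, far = compute_hr_far(results, truth)
    rng = hr_range_by_gop(results, truth, gop)
    roc_pts, auc = None, None
    if diffs is not None:
        try:
            roc_pts, auc = roc_curve(diffs, truth)
        except ROCError:
            pass
    return EvalReport(hr=hr, far=far, hr_range=rng, roc_points=roc_pts, auc=auc, gop=gop)
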