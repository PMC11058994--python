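"""Agreement metrics between predicted and reference lesion masks.

Per case: Dice similarity coefficient (with the conventional six
agreement bands), sensitivity, specificity, and a threshold-sweep
ROC-AUC.  Across a cohort: field-wise means/SDs and Lin's concordance
correlation coefficient (CCC) of predicted versus reference volumes with
an asymptotic 95% CI.

All voxel counting is restricted to a domain mask (here ROI intersected
with brain): counting true negatives over the whole scan would pin
specificity at ~1 regardless of segmentation quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adaptive_segmentation import ROIBox, RuleTable, DEFAULT_RULES, threshold_segment, ThresholdWindow
from .preprocessing import BrainMask
from .volume_io import BinaryMask, CTVolume

__all__ = [
    "CaseMetrics",
    "CohortMetrics",
    "confusion_counts",
    "dice",
    "agreement_band",
    "sensitivity_specificity",
    "roc_auc",
    "lins_ccc",
    "evaluate_case",
    "cohort_metrics",
]

AGREEMENT_BANDS = (
    (0.0, "none"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost-perfect"),
)


@dataclass(frozen=True)
class CaseMetrics:
    case_id: str
    dsc: float
    agreement_band: str
    auc: float  # NaN when undefined
    sensitivity: float  # NaN when TP + FN = 0
    specificity: float  # NaN when TN + FP = 0
    pred_volume_ml: float
    gt_volume_ml: float
    degenerate: bool = False  # both masks empty

    def to_dict(self) -> dict:
        def _clean(v):
            return None if isinstance(v, float) and np.isnan(v) else v

        return {
            "case_id": self.case_id,
            "dsc": round(self.dsc, 6),
            "agreement_band": self.agreement_band,
            "auc": _clean(round(self.auc, 6) if not np.isnan(self.auc) else self.auc),
            "sensitivity": _clean(self.sensitivity),
            "specificity": _clean(self.specificity),
            "pred_volume_ml": round(self.pred_volume_ml, 4),
            "gt_volume_ml": round(self.gt_volume_ml, 4),
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class CohortMetrics:
    n_cases: int
    mean: dict
    sd: dict
    lins_ccc: float
    ccc_ci95: tuple[float, float]


def _check_grids(*masks: BinaryMask) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks on different grids: {sorted(shapes)}")


def confusion_counts(
    pred: BinaryMask, gt: BinaryMask, domain: BinaryMask
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counted over the domain voxels only."""
    _check_grids(pred, gt, domain)
    d = domain.voxels
    p = pred.voxels & d
    g = gt.voxels & d
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(d)) - tp - fp - fn
    return tp, fp, fn, tn


def agreement_band(dsc: float) -> str:
    """Six-category verbal agreement band for a Dice score."""
    if dsc == 0.0:
        return "none"
    for upper, name in AGREEMENT_BANDS[1:-1]:
        if dsc < upper:
            return name
    return "almost-perfect"


def dice(pred: BinaryMask, gt: BinaryMask, domain: BinaryMask) -> tuple[float, str, bool]:
    """Dice coefficient 2TP / (2TP + FP + FN) with its agreement band.

    Returns ``(dsc, band, degenerate)``; two empty masks agree perfectly
    (dsc = 1) but are flagged degenerate.
    """
    tp, fp, fn, _ = confusion_counts(pred, gt, domain)
    if tp + fp + fn == 0:
        return 1.0, "almost-perfect", True
    d = 2.0 * tp / (2.0 * tp + fp + fn)
    return d, agreement_band(d), False


def sensitivity_specificity(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP); NaN when a denominator is zero."""
    tp, fp, fn, tn = counts
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return sens, spec


def roc_auc(
    vol: CTVolume,
    roi: ROIBox,
    brain: BrainMask,
    gt: BinaryMask,
    low_grid: np.ndarray | None = None,
    width: float = 30.0,
) -> float:
    """ROC-AUC of the windowed thresholder against the reference mask.

    A hard segmenter has no voxel score to sweep; its only scalar dial
    is the window position.  The lower bound L is swept over ``low_grid``
    (default -20..120 HU, step 1) at fixed width, giving one (FPR, TPR)
    operating point per L within ROI-intersect-brain.  The ROC curve is
    the monotone upper envelope of those points anchored at (0,0) and
    (1,1); the area under it is returned by trapezoidal integration.

    Returns NaN if the reference is empty (or fills the whole domain)
    within the ROI, where the ROC is undefined.
    """
    if low_grid is None:
        low_grid = np.arange(-20.0, 121.0, 1.0)
    domain = roi.support(vol.shape) & brain.voxels
    g = gt.voxels & domain
    n_pos = int(g.sum())
    n_neg = int(domain.sum()) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")

    pts = [(0.0, 0.0), (1.0, 1.0)]
    for low in low_grid:
        m = threshold_segment(vol, roi, brain, ThresholdWindow(low, low + width)).voxels
        tp = int(np.count_nonzero(m & g))
        fp = int(np.count_nonzero(m & domain & ~g))
        pts.append((fp / n_neg, tp / n_pos))

    pts.sort()
    fpr = np.array([p[0] for p in pts])
    tpr = np.maximum.accumulate(np.array([p[1] for p in pts]))
    return float(np.trapezoid(tpr, fpr))


def lins_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with asymptotic CI.

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), with
    population moments.  The CI uses the Fisher z-transform with Lin's
    asymptotic standard error.  Raises on n < 3 or zero total variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population variances
    sxy = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("zero total variance; CCC undefined")
    ccc = 2.0 * sxy / denom

    if vx == 0 or vy == 0:
        return float(ccc), (float("nan"), float("nan"))
    r = sxy / np.sqrt(vx * vy)
    # Lin's asymptotic variance of the z-transformed CCC
    u = (mx - my) / (vx * vy) ** 0.25
    c2 = ccc**2
    if abs(ccc) >= 1.0 or r == 0:
        return float(ccc), (float(ccc), float(ccc))
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - c2**2 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(ccc)
    from scipy.stats import norm

    half = norm.ppf(1 - alpha / 2) * np.sqrt(max(var_z, 0.0))
    return float(ccc), (float(np.tanh(z - half)), float(np.tanh(z + half)))


def evaluate_case(
    pred: BinaryMask,
    gt: BinaryMask,
    domain: BinaryMask,
    case_id: str = "",
    vol: CTVolume | None = None,
    roi: ROIBox | None = None,
    brain: BrainMask | None = None,
) -> CaseMetrics:
    """All per-case metrics; AUC is computed only when vol/roi/brain given."""
    from .volume_io import mask_volume_ml

    counts = confusion_counts(pred, gt, domain)
    dsc, band, degenerate = dice(pred, gt, domain)
    sens, spec = sensitivity_specificity(counts)
    auc = float("nan")
    if vol is not None and roi is not None and brain is not None:
        auc = roc_auc(vol, roi, brain, gt)
    return CaseMetrics(
        case_id=case_id,
        dsc=dsc,
        agreement_band=band,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        pred_volume_ml=mask_volume_ml(pred),
        gt_volume_ml=mask_volume_ml(gt),
        degenerate=degenerate,
    )


_NUMERIC_FIELDS = ("dsc", "auc", "sensitivity", "specificity", "pred_volume_ml", "gt_volume_ml")


def cohort_metrics(cases: list[CaseMetrics]) -> CohortMetrics:
    """Unweighted cohort means/SDs plus Lin's CCC of paired volumes."""
    if not cases:
        raise ValueError("empty cohort")
    mean, sd = {}, {}
    for f in _NUMERIC_FIELDS:
        vals = np.array([getattr(c, f) for c in cases], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        mean[f] = float(vals.mean()) if vals.size else float("nan")
        sd[f] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    pred_v = [c.pred_volume_ml for c in cases]
    gt_v = [c.gt_volume_ml for c in cases]
    try:
        ccc, ci = lins_ccc(pred_v, gt_v)
    except ValueError:
        ccc, ci = float("nan"), (float("nan"), float("nan"))
    return CohortMetrics(n_cases=len(cases), mean=mean, sd=sd, lins_ccc=ccc, ccc_ci95=ci)
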