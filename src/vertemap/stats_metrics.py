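"""Quantification statistics, segmentation-evaluation metrics and agreement.

Three groups of functionality:

* PDFF summaries (mean / min / max / SD) over masked voxels or over the
  valid pixels of standardized distribution maps.  SD is the voxel-wise
  inhomogeneity measure; the *sample* convention (n−1 denominator) is used
  throughout so volumetric and map-based values are directly comparable.
* Class-wise confusion-matrix metrics for comparing a predicted vertebra
  mask against a ground-truth mask (Dice, Jaccard, precision/recall and
  their complements FDR/FNR, specificity TNR/FPR, NPV/FOR, accuracy) plus
  the absolute and relative volumetric error.
* Method agreement and group comparison: Bland–Altman bias and limits of
  agreement for map-derived vs volumetric values, and a two-sample test
  that picks Welch's t-test when both samples pass Shapiro–Wilk normality
  and the Mann–Whitney U test otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import EmptyMaskError
from .inclination import VertebraROI
from .standardize import StandardizedMaps

__all__ = [
    "PDFFStats", "ConfusionMetrics", "BlandAltmanResult", "GroupTestResult",
    "volumetric_stats", "map_stats", "map_stats_per_plane",
    "confusion_metrics", "bland_altman", "compare_groups",
]


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


@dataclass(frozen=True)
class PDFFStats:
    """Mean / min / max / SD of PDFF values, all in percent."""

    mean: float
    min: float
    max: float
    sd: float
    n: int
    source: str  # "volumetric" | "maps_pooled" | "map_transverse" | ...

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")
        if self.sd < 0 or self.n < 1:
            raise ValueError("invalid sd or n")


def _stats_from(values: np.ndarray, source: str) -> PDFFStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyMaskError(f"no values for {source} statistics")
    return PDFFStats(
        mean=float(values.mean()), min=float(values.min()),
        max=float(values.max()), sd=_sample_sd(values),
        n=int(values.size), source=source,
    )


def volumetric_stats(roi: VertebraROI) -> PDFFStats:
    """Statistics over the scalar values at masked voxels only."""
    return _stats_from(roi.scalar[roi.mask], "volumetric")


def map_stats(maps: StandardizedMaps) -> PDFFStats:
    """Statistics over the valid pixels of all three maps, pooled."""
    return _stats_from(maps.valid_values(), "maps_pooled")


def map_stats_per_plane(maps: StandardizedMaps) -> dict[str, PDFFStats]:
    """Per-plane statistics keyed by plane name."""
    return {
        name: _stats_from(arr[ok], f"map_{name}")
        for name, (arr, ok) in maps.planes().items()
    }


# ---------------------------------------------------------------------------
# Segmentation evaluation


@dataclass(frozen=True)
class ConfusionMetrics:
    """Voxel-wise confusion-matrix metrics for one vertebra level.

    Fractions are NaN when their denominator is empty (e.g. precision with
    an empty prediction); ``rel_vol_error_percent`` is NaN when the ground
    truth is empty.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    dsc: float
    jaccard: float
    precision: float
    recall: float
    tnr: float
    npv: float
    fdr: float
    fnr: float
    fpr: float
    forate: float
    abs_vol_error_ml: float
    rel_vol_error_percent: float


def _frac(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(
    pred: np.ndarray, truth: np.ndarray, voxel_volume_ml: float
) -> ConfusionMetrics:
    """Compare a predicted binary mask against ground truth, voxel-wise."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    n_pred, n_truth = tp + fp, tp + fn
    abs_err_ml = abs(n_pred - n_truth) * voxel_volume_ml
    rel_err = (100.0 * abs_err_ml / (n_truth * voxel_volume_ml)
               if n_truth > 0 else float("nan"))
    return ConfusionMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=_frac(tp + tn, tp + fp + fn + tn),
        dsc=_frac(2 * tp, 2 * tp + fp + fn),
        jaccard=_frac(tp, tp + fp + fn),
        precision=_frac(tp, n_pred),
        recall=_frac(tp, n_truth),
        tnr=_frac(tn, tn + fp),
        npv=_frac(tn, tn + fn),
        fdr=_frac(fp, n_pred),
        fnr=_frac(fn, n_truth),
        fpr=_frac(fp, tn + fp),
        forate=_frac(fn, tn + fn),
        abs_vol_error_ml=abs_err_ml,
        rel_vol_error_percent=rel_err,
    )


# ---------------------------------------------------------------------------
# Agreement and group tests


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95 % limits of agreement of paired differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def bland_altman(volumetric, maps) -> BlandAltmanResult:
    """Bland–Altman agreement of map-derived against volumetric values.

    Differences are taken as ``maps − volumetric``, so a template that
    underestimates shows a negative bias.  Limits of agreement are
    ``bias ± 1.96·SD`` of the differences (sample SD).
    """
    a = np.asarray(volumetric, dtype=float)
    b = np.asarray(maps, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    bias = float(d.mean())
    sd = _sample_sd(d)
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd,
                             n_pairs=int(a.size))


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str           # "welch_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    alpha: float
    significant: bool


def _shapiro_p(sample: np.ndarray) -> float:
    """Shapiro–Wilk p-value; NaN when undefined (e.g. constant sample)."""
    if np.ptp(sample) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(sps.shapiro(sample).pvalue)
        except Exception:
            return float("nan")


def compare_groups(a, b, alpha: float = 0.05) -> GroupTestResult:
    """Two-sample comparison with a normality-gated test choice.

    Both samples are screened with Shapiro–Wilk at the same ``alpha``; if
    both look normal, Welch's t-test (unequal variances) is used, otherwise
    the two-sided Mann–Whitney U test.  Samples whose normality is
    undefined (constant values) fall back to Mann–Whitney.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = (pa >= alpha) and (pb >= alpha)  # False if either is NaN
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    p = float(res.pvalue)
    return GroupTestResult(
        test_name=name, statistic=float(res.statistic), p_value=p,
        normality_p=(pa, pb), alpha=alpha, significant=bool(p < alpha),
    )
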