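"""Classification metrics, the MLcps% composite score, permutation testing,
and the connected-component binarization rule used to compare against
segmentation methods.

MLcps% is the area of the pentagon spanned by the five metrics (accuracy,
sensitivity, specificity, F1, precision) on equally spaced radar axes,
normalized by the pentagon area when all five metrics are 100, times 100.
The area depends on the axis order; the order above is fixed and recorded in
every report.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .io import NEGATIVE, POSITIVE, rng_from

MLCPS_AXIS_ORDER = ("accuracy", "sensitivity", "specificity", "f1", "precision")


@dataclasses.dataclass
class MetricsReport:
    """Five metrics + AUROC + MLcps%, all in percent, with confusion counts.

    Metrics undefined for the given confusion (e.g. sensitivity with no
    positive truth) are NaN, never silently 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auroc: float                       # percent; NaN if scores unavailable
    mlcps_percent: float
    confusion: tuple[int, int, int, int]   # (TP, FP, TN, FN)
    mlcps_axis_order: tuple[str, ...] = MLCPS_AXIS_ORDER

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = dict(zip(("TP", "FP", "TN", "FN"), self.confusion))
        d["auroc_unit"] = "percent"
        return d


@dataclasses.dataclass
class PermutationResult:
    null_accuracies: np.ndarray
    observed_accuracy: float
    p_value: float
    n_permutations: int
    n_failed: int = 0


def _as_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "SUO":        # strings (incl. pandas object columns)
        arr = arr.astype(str)
        bad = set(np.unique(arr)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(bad)}")
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def compute_metrics(y_true, y_pred, y_score=None) -> MetricsReport:
    """Compute the report from truth/prediction labels and optional scores.

    Labels may be the string classes or {0,1}. All metrics are percentages;
    AUROC is reported in percent (unit recorded in the report dict).
    """
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    if len(t) != len(p):
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    if len(np.unique(t)) < 2:
        warnings.warn("single-class y_true: some metrics are undefined",
                      stacklevel=2)

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    accuracy = ratio(tp + tn, len(t))
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if np.isfinite(precision) and np.isfinite(sensitivity)
          and (precision + sensitivity) > 0 else float("nan"))
    if y_score is not None and len(np.unique(t)) == 2:
        auroc = 100.0 * float(roc_auc_score(t, np.asarray(y_score, float)))
    else:
        auroc = float("nan")
    five = (accuracy, sensitivity, specificity, f1, precision)
    mlcps = mlcps_percent(five) if all(np.isfinite(v) for v in five) else float("nan")
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, precision=precision, f1=f1,
                         auroc=auroc, mlcps_percent=mlcps,
                         confusion=(tp, fp, tn, fn))


def mlcps_percent(metrics: Sequence[float]) -> float:
    """Normalized pentagon radar area of the five metrics (percent).

    With radii r_1..r_5 on axes 72 degrees apart, the area is
    (1/2) sin(72deg) * sum_i r_i r_{i+1 (cyclic)}; the result is that area
    divided by the all-100 pentagon area, times 100.
    """
    r = np.asarray(metrics, dtype=float)
    if r.shape != (5,):
        raise ValueError(f"expected exactly 5 metrics, got shape {r.shape}")
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("metric values must lie in [0, 100]")
    cross = float(np.sum(r * np.roll(r, -1)))
    cross_max = 5 * 100.0 * 100.0
    return 100.0 * cross / cross_max


def permutation_test(pipeline_factory: Callable, train_set, val_set, test_set,
                     n_permutations: int = 1000, seed: int = 0,
                     observed_accuracy: float | None = None) -> PermutationResult:
    """Label-shuffling permutation test of classifier performance.

    ``pipeline_factory(seed)`` must return an object with
    ``fit(x, y, x_val, y_val)`` and ``score_accuracy(x, y)``. For each
    permutation the training (and validation) labels are shuffled jointly,
    the pipeline is retrained, and test accuracy recorded; the null
    distribution is compared with the observed accuracy via the add-one
    p-value (1 + #{null >= observed}) / (1 + n). If ``observed_accuracy`` is
    not given, the unshuffled pipeline is trained once to obtain it. A
    pipeline failure inside a permutation is recorded and excluded with a
    warning.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    xtr, ytr = train_set
    xva, yva = val_set
    xte, yte = test_set
    ytr = np.asarray(ytr)
    yva = np.asarray(yva)
    if observed_accuracy is None:
        pipe = pipeline_factory(rng_from(seed, "observed").integers(2**31))
        pipe.fit(xtr, ytr, xva, yva)
        observed_accuracy = float(pipe.score_accuracy(xte, yte))
    nulls: list[float] = []
    n_failed = 0
    labels = np.concatenate([ytr, yva])
    for i in range(n_permutations):
        rng = rng_from(seed, "perm", i)
        perm = labels[rng.permutation(len(labels))]
        ptr, pva = perm[:len(ytr)], perm[len(ytr):]
        try:
            pipe = pipeline_factory(rng_from(seed, "perm-model", i).integers(2**31))
            pipe.fit(xtr, ptr, xva, pva)
            nulls.append(float(pipe.score_accuracy(xte, yte)))
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            n_failed += 1
            warnings.warn(f"permutation {i} failed: {exc}", stacklevel=2)
    nulls_arr = np.asarray(nulls)
    p = (1 + int(np.sum(nulls_arr >= observed_accuracy))) / (1 + len(nulls_arr))
    return PermutationResult(null_accuracies=nulls_arr,
                             observed_accuracy=observed_accuracy,
                             p_value=float(p), n_permutations=len(nulls_arr),
                             n_failed=n_failed)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def binarize_segmentation(lesion_mask: np.ndarray, min_voxels: int = 5,
                          connectivity: int = 6) -> str:
    """Scan-level label from a segmentation mask: positive iff at least one
    connected lesion component has ``min_voxels`` or more voxels.

    Face connectivity (6) by default; 18 and 26 also supported.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(lesion_mask).astype(bool)
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return NEGATIVE
    sizes = np.bincount(labeled.ravel())[1:]
    return POSITIVE if sizes.max() >= min_voxels else NEGATIVE
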