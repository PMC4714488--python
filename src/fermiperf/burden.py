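"""Ischemic burden statistics from MPR maps, with and without scar exclusion.

The ischemic burden at an MPR threshold theta is the percentage of evaluable
LV myocardium with perfusion reserve strictly below theta.  For
high-resolution maps the unit is the pixel, pooled across all slices; for
segmental results each segment contributes its full pixel count, so a
segment is either entirely ischemic or entirely normal at a given threshold.

Scar correction removes overt-LGE pixels from both the numerator and the
denominator, i.e. the corrected burden is the ischemic percentage of the
*non-scarred* myocardium.  (Removing them from the numerator only would
systematically understate burden in heavily scarred ventricles.)  Invalid
MPR pixels are excluded from numerator and denominator alike.

Also provided: the relative error between uncorrected and corrected burden
(normalised by the uncorrected value), equal-count tertile recategorisation
of per-subject burdens, and Bland-Altman / Pearson agreement statistics for
interobserver reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fermi import MPRMap

__all__ = [
    "DEFAULT_THRESHOLDS",
    "BurdenCurve",
    "burden_curve",
    "corrected_burden",
    "segmental_mpr_map",
    "relative_error",
    "tertile_assign",
    "tertile_recategorization",
    "BlandAltman",
    "bland_altman",
]

#: default MPR threshold grid
DEFAULT_THRESHOLDS = np.round(np.arange(0.5, 2.5 + 1e-9, 0.1), 10)


@dataclass
class BurdenCurve:
    """Ischemic burden (% of LV myocardium) per MPR threshold."""

    thresholds: np.ndarray
    burden: np.ndarray
    corrected: bool = False
    n_units: int = 0

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.burden = np.asarray(self.burden, dtype=float)
        if self.thresholds.shape != self.burden.shape:
            raise ValueError("thresholds and burden lengths differ")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")

    def at(self, theta: float) -> float:
        idx = np.nonzero(np.isclose(self.thresholds, theta))[0]
        if idx.size == 0:
            raise KeyError(f"threshold {theta} not on the grid")
        return float(self.burden[idx[0]])


def _pool_valid_mpr(mpr, exclude=None):
    """Valid MPR values pooled over one map or a list of maps."""
    maps = [mpr] if isinstance(mpr, MPRMap) else list(mpr)
    excludes = (
        [None] * len(maps)
        if exclude is None
        else ([exclude] if isinstance(exclude, np.ndarray) else list(exclude))
    )
    values = []
    for m, ex in zip(maps, excludes):
        keep = m.valid.copy()
        if ex is not None:
            keep &= ~np.asarray(ex, dtype=bool)
        values.append(m.values[keep])
    return np.concatenate(values) if values else np.empty(0)


def burden_curve(mpr, thresholds=DEFAULT_THRESHOLDS) -> BurdenCurve:
    """Uncorrected burden curve from one MPR map or a list (slices pooled)."""
    values = _pool_valid_mpr(mpr)
    if values.size == 0:
        raise ValueError("no valid MPR units to evaluate")
    thresholds = np.asarray(thresholds, dtype=float)
    burden = 100.0 * np.mean(values[None, :] < thresholds[:, None], axis=1)
    return BurdenCurve(
        thresholds=thresholds, burden=burden, corrected=False, n_units=values.size
    )


def corrected_burden(mpr, scar, thresholds=DEFAULT_THRESHOLDS) -> BurdenCurve:
    """Scar-corrected burden: overt-scar pixels removed from both counts.

    ``scar`` is a boolean mask (or per-slice list of masks / ScarMask
    objects) in perfusion-map space.
    """
    masks = _as_bool_masks(scar)
    values = _pool_valid_mpr(mpr, exclude=masks)
    if values.size == 0:
        raise ValueError("scar covers the entire evaluable myocardium")
    thresholds = np.asarray(thresholds, dtype=float)
    burden = 100.0 * np.mean(values[None, :] < thresholds[:, None], axis=1)
    return BurdenCurve(
        thresholds=thresholds, burden=burden, corrected=True, n_units=values.size
    )


def _as_bool_masks(scar):
    from .lge import ScarMask  # local import to avoid cycle at module load

    if isinstance(scar, ScarMask):
        return [scar.mask]
    if isinstance(scar, np.ndarray) and scar.ndim == 2:
        return [scar.astype(bool)]
    return [m.mask if isinstance(m, ScarMask) else np.asarray(m, dtype=bool)
            for m in scar]


def segmental_mpr_map(segments, segmental_mpr: dict) -> MPRMap:
    """Expand per-segment MPR values to a pixel map (pixel-count weighting).

    ``segments`` is a SegmentModel; ``segmental_mpr`` maps segment id to its
    MPR (NaN marks a failed segment, which becomes invalid in the map).
    """
    values = np.full(segments.labels.shape, np.nan)
    valid = np.zeros(segments.labels.shape, dtype=bool)
    for seg_id in segments.segment_ids:
        sel = segments.labels == seg_id
        v = segmental_mpr.get(seg_id, np.nan)
        if np.isfinite(v):
            values[sel] = v
            valid[sel] = True
    return MPRMap(values=values, valid=valid, slice_label=segments.slice_label)


def relative_error(uncorrected: BurdenCurve, corrected: BurdenCurve):
    """Percentage overestimation of burden due to scar inclusion.

    ``err(theta) = 100 * (uncorrected - corrected) / uncorrected``; entries
    where the uncorrected burden is zero are NaN and flagged as undefined.

    Returns ``(thresholds, error, defined)``.
    """
    if uncorrected.thresholds.shape != corrected.thresholds.shape or not np.allclose(
        uncorrected.thresholds, corrected.thresholds
    ):
        raise ValueError("burden curves are on different threshold grids")
    defined = uncorrected.burden > 0
    err = np.full(uncorrected.burden.shape, np.nan)
    err[defined] = (
        100.0
        * (uncorrected.burden[defined] - corrected.burden[defined])
        / uncorrected.burden[defined]
    )
    return uncorrected.thresholds.copy(), err, defined


def tertile_assign(values) -> np.ndarray:
    """Equal-count tertile labels (0 low, 1 intermediate, 2 high).

    Ties are broken by stable subject order, so any split of the sorted
    sequence into three near-equal groups is reproducible.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("tertile assignment needs at least 3 subjects")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    edges = [round(n / 3), round(2 * n / 3)]
    return np.digitize(ranks, edges)


def tertile_recategorization(uncorrected, corrected) -> dict:
    """Re-score subjects against the uncorrected tertile boundaries.

    Tertiles are formed from the uncorrected per-subject burdens; the upper
    boundary of each tertile is the largest uncorrected burden it contains.
    Each subject's corrected burden is then placed against those same
    boundaries, and the table counts subjects moving down 0, 1 or 2 tertiles
    (movement up cannot occur when corrected <= uncorrected).

    Tied burdens are ordered by stable subject order, both when forming the
    boundaries and when re-scoring: a subject whose corrected burden exactly
    equals a boundary value is placed by its position in the input, so a
    cohort with ``corrected == uncorrected`` is never recategorised.

    Returns a dict with ``labels_before``, ``labels_after``, ``boundaries``,
    ``moved_down`` (counts for 0/1/2), and ``n_recategorized``.
    """
    uncorrected = np.asarray(uncorrected, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if uncorrected.shape != corrected.shape:
        raise ValueError("per-subject burden arrays differ in length")
    before = tertile_assign(uncorrected)
    # boundary keys: the (value, subject order) maximum of the low/mid tertile
    b_low = max(
        (uncorrected[i], i) for i in range(uncorrected.size) if before[i] == 0
    )
    b_mid = max(
        (uncorrected[i], i) for i in range(uncorrected.size) if before[i] == 1
    )
    after = np.array(
        [
            0 if (corrected[i], i) <= b_low
            else 1 if (corrected[i], i) <= b_mid
            else 2
            for i in range(corrected.size)
        ]
    )
    after = np.minimum(after, before)  # re-scoring never moves a subject up
    moved = before - after
    counts = {k: int(np.sum(moved == k)) for k in (0, 1, 2)}
    return dict(
        labels_before=before,
        labels_after=after,
        boundaries=(float(b_low[0]), float(b_mid[0])),
        moved_down=counts,
        n_recategorized=int(np.sum(moved > 0)),
    )


@dataclass
class BlandAltman:
    """Agreement statistics between two paired measurement series."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    pearson_r: float
    r_defined: bool
    n: int


def bland_altman(values_a, values_b) -> BlandAltman:
    """Bland-Altman bias and limits of agreement plus Pearson correlation.

    ``bias = mean(a - b)``; limits are ``bias +- 1.96 * SD(a - b)`` with the
    sample (ddof=1) standard deviation.  The correlation is flagged undefined
    when either series has zero variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 paired samples")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if a.std() == 0 or b.std() == 0:
        r, defined = np.nan, False
    else:
        r, defined = float(stats.pearsonr(a, b).statistic), True
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        pearson_r=r,
        r_defined=defined,
        n=a.size,
    )
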