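"""Late gadolinium enhancement (LGE) scar segmentation and extent summary.

Overt scar is defined by signal intensity more than ``n_sd`` standard
deviations (default 6) above the mean of an operator-chosen remote,
non-enhanced myocardial region.  The comparison is strict: a pixel exactly at
the threshold is not scar.  No connected-component filtering is applied by
default; a minimum-size post-filter is available but off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects
from sklearn.base import BaseEstimator

from .geometry import ContourSet

__all__ = [
    "LGEImage",
    "ScarMask",
    "ScarSegmenter",
    "segment_scar",
    "lge_percent",
    "interobserver_masks",
]


@dataclass
class LGEImage:
    """A 2-D LGE image with its contours and remote reference region."""

    image: np.ndarray
    contours: ContourSet
    remote_mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.remote_mask = np.asarray(self.remote_mask, dtype=bool)
        if self.image.ndim != 2:
            raise ValueError("LGE image must be 2-D")
        if self.remote_mask.shape != self.image.shape:
            raise ValueError("remote mask shape does not match the image")
        if not self.remote_mask.any():
            raise ValueError("remote ROI is empty")

    @property
    def myocardium(self) -> np.ndarray:
        return self.contours.annulus_mask(self.image.shape)


@dataclass
class ScarMask:
    """Per-pixel overt-scar label within the myocardial annulus."""

    mask: np.ndarray
    space: str = "lge"  # or "perfusion"
    threshold: float = np.nan

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


class ScarSegmenter(BaseEstimator):
    """SD-threshold scar segmentation as a scikit-learn style estimator.

    ``fit`` learns the remote-region statistics; ``predict`` labels
    myocardial pixels strictly above ``mean + n_sd * SD``.

    Parameters
    ----------
    n_sd : float
        Threshold multiplier in remote standard deviations (default 6).
    min_size : int
        Optional minimum scar component size in pixels (0 disables the
        filter, the default convention).

    Attributes
    ----------
    remote_mean_, remote_sd_ : float
    threshold_ : float
        ``remote_mean_ + n_sd * remote_sd_``.
    """

    def __init__(self, n_sd: float = 6.0, min_size: int = 0):
        self.n_sd = n_sd
        self.min_size = min_size

    def fit(self, image, remote_mask):
        if not self.n_sd > 0:
            raise ValueError("n_sd must be positive")
        image = np.asarray(image, dtype=float)
        remote = np.asarray(remote_mask, dtype=bool)
        if not remote.any():
            raise ValueError("remote ROI is empty")
        values = image[remote]
        self.remote_mean_ = float(values.mean())
        self.remote_sd_ = float(values.std(ddof=1)) if values.size > 1 else 0.0
        self.threshold_ = self.remote_mean_ + self.n_sd * self.remote_sd_
        return self

    def predict(self, image, myocardium_mask) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        myo = np.asarray(myocardium_mask, dtype=bool)
        scar = myo & (image > self.threshold_)
        if self.remote_sd_ == 0.0 and not scar.any():
            warnings.warn(
                "remote ROI has zero variance and no pixel exceeds its mean; "
                "returning an empty scar mask"
            )
        if self.min_size > 0 and scar.any():
            scar = remove_small_objects(scar, min_size=self.min_size)
        return scar


def segment_scar(lge: LGEImage, n_sd: float = 6.0, min_size: int = 0) -> ScarMask:
    """Threshold-based overt-scar segmentation of one LGE image."""
    est = ScarSegmenter(n_sd=n_sd, min_size=min_size)
    est.fit(lge.image, lge.remote_mask)
    mask = est.predict(lge.image, lge.myocardium)
    return ScarMask(mask=mask, space="lge", threshold=est.threshold_)


def lge_percent(scar_masks, myocardium_masks) -> float:
    """Scar extent as percent of myocardial pixel area over all slices."""
    scar_masks = _as_mask_list(scar_masks)
    myocardium_masks = _as_mask_list(myocardium_masks)
    n_myo = sum(int(m.sum()) for m in myocardium_masks)
    if n_myo == 0:
        raise ValueError("myocardium is empty")
    n_scar = sum(int(m.sum()) for m in scar_masks)
    return 100.0 * n_scar / n_myo


def _as_mask_list(masks):
    if isinstance(masks, ScarMask):
        return [masks.mask]
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        return [np.asarray(masks, dtype=bool)]
    return [m.mask if isinstance(m, ScarMask) else np.asarray(m, dtype=bool)
            for m in masks]


def interobserver_masks(
    lge: LGEImage,
    remote_a: np.ndarray,
    remote_b: np.ndarray,
    n_sd: float = 6.0,
):
    """Scar masks from two observers' remote-region choices.

    Each observer's remote ROI yields its own threshold and scar mask; the
    downstream corrected burdens per mask feed Bland-Altman reproducibility
    analysis.
    """
    masks = []
    for remote in (remote_a, remote_b):
        est = ScarSegmenter(n_sd=n_sd).fit(lge.image, remote)
        masks.append(
            ScarMask(
                mask=est.predict(lge.image, lge.myocardium),
                space="lge",
                threshold=est.threshold_,
            )
        )
    return tuple(masks)
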