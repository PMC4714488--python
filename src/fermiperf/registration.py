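"""Transfer of the scar mask from LGE geometry into perfusion-map geometry.

LGE and perfusion slices are acquired in different cardiac phases, so their
contours differ.  Rather than a deformable registration, the annulus is put
into a contour-normalised polar frame: each myocardial pixel is described by
its counter-clockwise angle relative to the RV-insertion reference and its
transmural depth fraction between the endo- and epicardial contours.  These
two coordinates are preserved across geometries, which is exactly the
normalisation a deformable template achieves for annular masks, but
deterministic and directly testable on analytic annuli.

The transfer is implemented pull-style: every perfusion myocardial pixel
looks up its (angle, depth) twin in LGE space and takes the scar label of the
nearest LGE pixel.  The output is therefore a subset of the perfusion
myocardium by construction, and identical contour sets give an identity
transfer.
"""

from __future__ import annotations

import numpy as np

from .geometry import ContourSet
from .lge import ScarMask

__all__ = ["align_lge_to_perfusion"]


def align_lge_to_perfusion(
    lge_contours: ContourSet,
    perf_contours: ContourSet,
    scar: ScarMask,
    perf_shape=None,
) -> ScarMask:
    """Map an LGE-space scar mask into perfusion-map space.

    Parameters
    ----------
    lge_contours, perf_contours : ContourSet
        Contours of the matched LGE and perfusion slices.
    scar : ScarMask
        Scar labels on the LGE pixel grid (subset of the LGE myocardium).
    perf_shape : tuple, optional
        Perfusion grid shape; defaults to the LGE grid shape.

    Returns
    -------
    ScarMask
        Scar labels on the perfusion grid, ``space="perfusion"``.
    """
    scar_arr = np.asarray(scar.mask, dtype=bool)
    lge_shape = scar_arr.shape
    perf_shape = lge_shape if perf_shape is None else tuple(perf_shape)

    perf_myo = perf_contours.annulus_mask(perf_shape)  # raises when empty
    out = np.zeros(perf_shape, dtype=bool)
    if not scar_arr.any():
        return ScarMask(mask=out, space="perfusion", threshold=scar.threshold)

    rows, cols = np.nonzero(perf_myo)
    rel, depth = perf_contours.polar_coordinates(np.stack([rows, cols], axis=1))
    targets = lge_contours.point_at(rel, depth)
    t_rows = np.clip(np.rint(targets[:, 0]).astype(int), 0, lge_shape[0] - 1)
    t_cols = np.clip(np.rint(targets[:, 1]).astype(int), 0, lge_shape[1] - 1)
    out[rows, cols] = scar_arr[t_rows, t_cols]
    return ScarMask(mask=out, space="perfusion", threshold=scar.threshold)
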