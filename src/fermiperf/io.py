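"""File interfaces: NIfTI image stacks, CSV curves/tables, JSON contours, YAML specs.

A simulated subject is laid out on disk as::

    <dir>/spec.yaml                      phantom specification
    <dir>/aif.csv                        low-dose AIF (time_s, value)
    <dir>/perf_<state>_<slice>.nii.gz    4-D perfusion stack (time last)
    <dir>/lge_<slice>.nii.gz             LGE image
    <dir>/remote_<slice>.nii.gz          remote ROI mask
    <dir>/contours_<slice>.json          endo/epi polylines + reference angle
    <dir>/truth_<...>.nii.gz             true MBF/MPR fields and scar masks
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fermi import Curve
from .geometry import ContourSet
from .lge import LGEImage
from .phantom import (
    AifSpec,
    PhantomSpec,
    RegionSpec,
    ScarSpec,
    SubjectPhantom,
    phantom_truth,
)
from .preprocess import PerfusionSeries

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_series_nifti",
    "read_series_nifti",
    "write_image_nifti",
    "read_image_nifti",
    "write_contours_json",
    "read_contours_json",
    "spec_to_dict",
    "spec_from_dict",
    "write_spec_yaml",
    "read_spec_yaml",
    "write_subject",
    "load_subject",
]


def write_curve_csv(curve: Curve, path, value_name: str = "value"):
    pd.DataFrame({"time_s": curve.times, value_name: curve.values}).to_csv(
        path, index=False
    )


def read_curve_csv(path) -> Curve:
    df = pd.read_csv(path)
    return Curve(times=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy())


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = spacing_mm
    return aff


def write_series_nifti(series: PerfusionSeries, path, spacing_mm: float = 1.0):
    """Write a perfusion series with time as the 4th dimension."""
    data = np.moveaxis(series.frames, 0, -1)[:, :, None, :]
    img = nib.Nifti1Image(data.astype(np.float32), _affine(spacing_mm))
    img.header["pixdim"][4] = series.dt
    nib.save(img, str(path))


def read_series_nifti(path, slice_label: str = "", state: str = "") -> PerfusionSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    frames = np.moveaxis(data[:, :, 0, :], -1, 0)
    dt = float(img.header["pixdim"][4]) or 1.0
    times = np.arange(frames.shape[0]) * dt
    return PerfusionSeries(frames=frames, times=times,
                           slice_label=slice_label, state=state)


def write_image_nifti(image: np.ndarray, path, spacing_mm: float = 1.0):
    arr = np.asarray(image)
    dtype = np.uint8 if arr.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(arr.astype(dtype), _affine(spacing_mm)), str(path))


def read_image_nifti(path, as_bool: bool = False) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    return data.astype(bool) if as_bool else data.astype(float)


def write_contours_json(contours: ContourSet, path):
    payload = {
        "endo": contours.endo.tolist(),
        "epi": contours.epi.tolist(),
        "reference_angle": contours.reference_angle,
    }
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path) -> ContourSet:
    payload = json.loads(Path(path).read_text())
    return ContourSet(
        endo=np.asarray(payload["endo"]),
        epi=np.asarray(payload["epi"]),
        reference_angle=float(payload["reference_angle"]),
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d.pop("stress_mbf_fields", None)
    d.pop("rest_mbf_fields", None)
    for key in ("shape", "slice_labels", "endo_radii_mm", "epi_radii_mm"):
        d[key] = list(d[key])
    for region in ("defect", "scar"):
        if d[region] is not None:
            d[region]["depth_range"] = list(d[region]["depth_range"])
            d[region]["slices"] = list(d[region]["slices"])
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if d.get("aif") is not None and not isinstance(d["aif"], AifSpec):
        d["aif"] = AifSpec(**d["aif"])
    if d.get("defect") is not None and not isinstance(d["defect"], RegionSpec):
        sub = dict(d["defect"])
        sub["depth_range"] = tuple(sub.get("depth_range", (0.0, 0.5)))
        sub["slices"] = tuple(sub.get("slices", (0, 1, 2)))
        d["defect"] = RegionSpec(**sub)
    if d.get("scar") is not None and not isinstance(d["scar"], ScarSpec):
        sub = dict(d["scar"])
        sub["depth_range"] = tuple(sub.get("depth_range", (0.2, 0.8)))
        sub["slices"] = tuple(sub.get("slices", (0, 1)))
        d["scar"] = ScarSpec(**sub)
    for key in ("shape", "slice_labels", "endo_radii_mm", "epi_radii_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def write_spec_yaml(spec: PhantomSpec, path):
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))


def read_spec_yaml(path) -> PhantomSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


def write_subject(subject: SubjectPhantom, out_dir):
    """Write a simulated subject to disk in the documented layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = subject.spec
    write_spec_yaml(spec, out / "spec.yaml")
    write_curve_csv(subject.aif, out / "aif.csv", value_name="aif")
    for state, series_list in (("stress", subject.stress), ("rest", subject.rest)):
        for series in series_list:
            write_series_nifti(
                series,
                out / f"perf_{state}_{series.slice_label}.nii.gz",
                spec.pixel_spacing_mm,
            )
    for i, label in enumerate(spec.slice_labels):
        write_image_nifti(
            subject.lge[i].image, out / f"lge_{label}.nii.gz", spec.pixel_spacing_mm
        )
        write_image_nifti(
            subject.remote_masks[i], out / f"remote_{label}.nii.gz",
            spec.pixel_spacing_mm,
        )
        write_contours_json(subject.truth.contours[i], out / f"contours_{label}.json")
        write_image_nifti(
            subject.truth.scar_masks[i], out / f"truth_scar_{label}.nii.gz",
            spec.pixel_spacing_mm,
        )
        write_image_nifti(
            np.nan_to_num(subject.truth.mpr[i], nan=0.0),
            out / f"truth_mpr_{label}.nii.gz",
            spec.pixel_spacing_mm,
        )


def load_subject(in_dir) -> SubjectPhantom:
    """Reload a subject written by :func:`write_subject`.

    The perfusion/LGE images come from disk; the deterministic truth is
    reconstructed from the stored spec.
    """
    src = Path(in_dir)
    spec = read_spec_yaml(src / "spec.yaml")
    aif = read_curve_csv(src / "aif.csv")
    truth = phantom_truth(spec)
    stress, rest, lge_images, remotes = [], [], [], []
    for i, label in enumerate(spec.slice_labels):
        stress.append(
            read_series_nifti(src / f"perf_stress_{label}.nii.gz", label, "stress")
        )
        rest.append(read_series_nifti(src / f"perf_rest_{label}.nii.gz", label, "rest"))
        remote = read_image_nifti(src / f"remote_{label}.nii.gz", as_bool=True)
        lge_images.append(
            LGEImage(
                image=read_image_nifti(src / f"lge_{label}.nii.gz"),
                contours=read_contours_json(src / f"contours_{label}.json"),
                remote_mask=remote,
            )
        )
        remotes.append(remote)
    return SubjectPhantom(
        spec=spec, stress=stress, rest=rest, aif=aif,
        lge=lge_images, remote_masks=remotes, truth=truth,
    )
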