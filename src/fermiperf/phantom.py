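"""Ground-truthed synthetic first-pass perfusion phantom.

The phantom emulates a three-slice short-axis stress/rest perfusion
acquisition with one frame per heartbeat, together with a matched LGE image
per slice and endo/epicardial contours, so that every downstream stage can be
tested against a known truth without any external data.

Forward model
-------------
The arterial input is a gamma-variate,

    c_a(t) = A * ((t - t0)/beta)**alpha * exp(-(t - t0)/beta)   for t > t0,

the standard convention for a compact first-pass bolus; the returned AIF is
the low-dose pre-bolus curve of a dual-bolus protocol and the tissue sees the
full-dose input ``dose_ratio * c_a``.  Every myocardial pixel's time course is

    s(t) = baseline + (c_a_full * h)(t) * dt + noise,

with a Fermi impulse response whose initial height equals the pixel's true
MBF; all pixels share the washout and shoulder shape parameters (k, tau0) and
the arrival delay tau_d, so the ground truth is unambiguous.  Blood-pool
pixels carry the full-dose AIF.  Noise is zero-mean Gaussian on magnitude
(adequate at first-pass SNR), optionally expressed through a target SNR
defined as peak mean myocardial enhancement over noise SD.  Optional
inter-frame translation jitter (integer pixels, applied by circular rolling)
emulates respiratory motion, and a smooth multiplicative bias field emulates
surface-coil inhomogeneity.

LGE images put remote myocardium at Normal(mu, sd) and scar pixels at
``mu + offset * sd`` with ``offset > 6`` by default, so the 6-SD rule is
recoverable; scar regions also get locally depressed stress MBF in the
perfusion truth.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .fermi import Curve, FermiParams, fermi_model_curve
from .geometry import ContourSet, circular_contours
from .lge import LGEImage
from .preprocess import PerfusionSeries

__all__ = [
    "AifSpec",
    "RegionSpec",
    "ScarSpec",
    "PhantomSpec",
    "PhantomTruth",
    "SubjectPhantom",
    "generate_aif",
    "generate_tissue_curve",
    "generate_perfusion_series",
    "generate_lge_image",
    "generate_subject",
    "generate_cohort",
    "correction_analysis_spec",
    "smooth_bias_field",
    "slice_contours",
    "mbf_fields",
    "scar_masks",
    "region_mask",
    "remote_roi",
    "phantom_truth",
]

_STATE_STREAM = {"rest": 0, "stress": 1}
_LGE_STREAM = 2


@dataclass(frozen=True)
class AifSpec:
    """Gamma-variate arterial input parameters (low-dose pre-bolus)."""

    amplitude: float = 1.0
    t0: float = 4.0
    alpha: float = 2.0
    beta: float = 3.0
    dose_ratio: float = 10.0

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.alpha > 0 or not self.beta > 0:
            raise ValueError("alpha and beta must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if not self.dose_ratio > 0:
            raise ValueError("dose_ratio must be > 0")


def generate_aif(spec: AifSpec, n_frames: int, dt: float) -> Curve:
    """Sample the gamma-variate AIF at t = 0, dt, ..., (n_frames-1)*dt.

    The curve peaks at ``t0 + alpha * beta`` with value
    ``amplitude * alpha**alpha * exp(-alpha)``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    t = np.arange(n_frames) * dt
    tau = (t - spec.t0) / spec.beta
    with np.errstate(invalid="ignore"):
        values = np.where(
            tau > 0, spec.amplitude * tau**spec.alpha * np.exp(-tau), 0.0
        )
    return Curve(times=t, values=values)


def generate_tissue_curve(aif: Curve, params: FermiParams, dt: float) -> Curve:
    """Forward model: causal convolution of the AIF with a Fermi response."""
    if abs(aif.dt - dt) > 0.01 * dt:
        raise ValueError("aif sampling interval does not match dt")
    values = fermi_model_curve(aif.values, params, dt)
    return Curve(times=aif.times.copy(), values=values)


@dataclass(frozen=True)
class RegionSpec:
    """An angular/transmural region of the annulus with its own stress MBF.

    Angles are relative to the RV-insertion reference, counter-clockwise, in
    radians; depth fractions run from 0 (endo) to 1 (epi).  Used for
    LGE-negative hypoperfusion (e.g. subendocardial defects).
    """

    angle_start: float = 0.0
    angle_width: float = np.pi / 3
    depth_range: tuple = (0.0, 0.5)
    slices: tuple = (0, 1, 2)
    stress_mbf: float = 1.3
    rest_mbf: float | None = None


@dataclass(frozen=True)
class ScarSpec(RegionSpec):
    """Overt-scar region: bright on LGE, depressed stress MBF.

    ``lge_offset_sd`` is the scar mean elevation in remote-SD units (> 6 by
    default so the 6-SD rule recovers it).  ``peri_angle`` optionally extends
    a peri-scar band of moderately reduced stress MBF on both sides.
    """

    depth_range: tuple = (0.2, 0.8)
    slices: tuple = (0, 1)
    stress_mbf: float = 0.7
    lge_offset_sd: float = 10.0
    peri_angle: float = 0.0
    peri_stress_mbf: float | None = None
    rim_offset_sd: float | None = None
    rim_depth_frac: float = 0.3

    def __post_init__(self):
        if not self.lge_offset_sd > 0:
            raise ValueError("lge_offset_sd must be > 0")
        if self.rim_offset_sd is not None and not self.rim_offset_sd > 0:
            raise ValueError("rim_offset_sd must be > 0 when set")


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of a synthetic subject.

    Radii are in mm; the grid is square with isotropic in-plane spacing.
    ``n_frames`` frames are acquired at ``dt`` seconds per heartbeat for the
    three slices (basal, mid, apical).  ``stress_mbf_fields`` /
    ``rest_mbf_fields`` may override the region-based truth with explicit
    per-pixel fields (NaN outside the annulus is tolerated).
    """

    shape: tuple = (64, 64)
    pixel_spacing_mm: float = 1.2
    slice_labels: tuple = ("basal", "mid", "apical")
    endo_radii_mm: tuple = (18.0, 16.0, 12.0)
    epi_radii_mm: tuple = (27.0, 25.0, 19.0)
    n_frames: int = 60
    dt: float = 1.0
    aif: AifSpec = field(default_factory=AifSpec)
    k: float = 0.3
    tau0: float = 5.0
    tau_d: float = 2.0
    rest_mbf: float = 1.0
    stress_mbf: float = 3.0
    defect: RegionSpec | None = None
    scar: ScarSpec | None = None
    baseline: float = 10.0
    noise_sigma: float = 0.0
    snr: float | None = None
    jitter_px: int = 0
    bias_strength: float = 0.0
    lge_remote_mean: float = 100.0
    lge_remote_sd: float = 10.0
    reference_angle: float = 0.0
    seed: int = 0
    stress_mbf_fields: tuple | None = field(default=None, compare=False)
    rest_mbf_fields: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if len(self.endo_radii_mm) != len(self.slice_labels) or len(
            self.epi_radii_mm
        ) != len(self.slice_labels):
            raise ValueError("one endo/epi radius pair per slice is required")
        for r_in, r_out in zip(self.endo_radii_mm, self.epi_radii_mm):
            if not 0 < r_in < r_out:
                raise ValueError("need 0 < endo radius < epi radius per slice")
        if not self.rest_mbf > 0 or not self.stress_mbf > 0:
            raise ValueError("true MBF values must be strictly positive")
        if self.jitter_px < 0:
            raise ValueError("jitter amplitude must be >= 0")

    @property
    def n_slices(self) -> int:
        return len(self.slice_labels)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic subject."""

    mbf_rest: list
    mbf_stress: list
    mpr: list
    scar_masks: list
    contours: list
    seed: int
    jitter_shifts: dict = field(default_factory=dict)

    def annulus_masks(self, shape) -> list:
        return [c.annulus_mask(shape) for c in self.contours]


def slice_contours(spec: PhantomSpec) -> list:
    """Concentric circular contours per slice, centred on the grid."""
    center = ((spec.shape[0] - 1) / 2.0, (spec.shape[1] - 1) / 2.0)
    out = []
    for r_in, r_out in zip(spec.endo_radii_mm, spec.epi_radii_mm):
        out.append(
            circular_contours(
                center,
                r_in / spec.pixel_spacing_mm,
                r_out / spec.pixel_spacing_mm,
                reference_angle=spec.reference_angle,
            )
        )
    return out


def region_mask(
    contours: ContourSet,
    shape,
    angle_start: float,
    angle_width: float,
    depth_range=(0.0, 1.0),
) -> np.ndarray:
    """Annulus pixels within an angular sector and transmural depth band."""
    annulus = contours.annulus_mask(shape)
    rows, cols = np.nonzero(annulus)
    rel, depth = contours.polar_coordinates(np.stack([rows, cols], axis=1))
    in_angle = np.mod(rel - angle_start, 2 * np.pi) < angle_width
    in_depth = (depth >= depth_range[0]) & (depth < depth_range[1])
    mask = np.zeros(shape, dtype=bool)
    mask[rows[in_angle & in_depth], cols[in_angle & in_depth]] = True
    return mask


def scar_masks(spec: PhantomSpec) -> list:
    """True overt-scar mask per slice (empty arrays when no scar)."""
    contours = slice_contours(spec)
    masks = []
    for i, c in enumerate(contours):
        if spec.scar is not None and i in spec.scar.slices:
            masks.append(
                region_mask(
                    c,
                    spec.shape,
                    spec.scar.angle_start,
                    spec.scar.angle_width,
                    spec.scar.depth_range,
                )
            )
        else:
            masks.append(np.zeros(spec.shape, dtype=bool))
    return masks


def _apply_region(field_arr, contours, spec_shape, region: RegionSpec, value, slice_idx):
    if value is None or slice_idx not in region.slices:
        return
    mask = region_mask(
        contours, spec_shape, region.angle_start, region.angle_width,
        region.depth_range,
    )
    field_arr[mask] = value


def mbf_fields(spec: PhantomSpec, state: str) -> list:
    """True per-pixel MBF field per slice (NaN outside the annulus)."""
    if state not in ("rest", "stress"):
        raise ValueError("state must be 'rest' or 'stress'")
    override = spec.rest_mbf_fields if state == "rest" else spec.stress_mbf_fields
    contours = slice_contours(spec)
    fields = []
    for i, c in enumerate(contours):
        annulus = c.annulus_mask(spec.shape)
        if override is not None:
            f = np.asarray(override[i], dtype=float).copy()
            if f.shape != spec.shape:
                raise ValueError("override MBF field shape mismatch")
            vals = f[annulus]
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError("override MBF must be positive inside annulus")
            f[~annulus] = np.nan
            fields.append(f)
            continue
        base = spec.rest_mbf if state == "rest" else spec.stress_mbf
        f = np.full(spec.shape, np.nan)
        f[annulus] = base
        if spec.defect is not None:
            value = (
                spec.defect.rest_mbf if state == "rest" else spec.defect.stress_mbf
            )
            _apply_region(f, c, spec.shape, spec.defect, value, i)
        if spec.scar is not None:
            if state == "stress" and spec.scar.peri_angle > 0:
                peri_value = spec.scar.peri_stress_mbf
                for side_start in (
                    spec.scar.angle_start - spec.scar.peri_angle,
                    spec.scar.angle_start + spec.scar.angle_width,
                ):
                    _apply_region(
                        f, c, spec.shape,
                        dataclasses.replace(
                            spec.scar,
                            angle_start=side_start,
                            angle_width=spec.scar.peri_angle,
                        ),
                        peri_value, i,
                    )
            value = spec.scar.rest_mbf if state == "rest" else spec.scar.stress_mbf
            _apply_region(f, c, spec.shape, spec.scar, value, i)
        fields.append(f)
    return fields


def phantom_truth(spec: PhantomSpec) -> PhantomTruth:
    """Assemble the deterministic ground truth for a spec."""
    rest = mbf_fields(spec, "rest")
    stress = mbf_fields(spec, "stress")
    mpr = [s / r for s, r in zip(stress, rest)]
    contours = slice_contours(spec)
    scars = scar_masks(spec)
    for s, c in zip(scars, contours):
        if s.any() and not (s <= c.annulus_mask(spec.shape)).all():
            raise ValueError("scar mask extends outside the myocardial annulus")
    return PhantomTruth(
        mbf_rest=rest,
        mbf_stress=stress,
        mpr=mpr,
        scar_masks=scars,
        contours=contours,
        seed=spec.seed,
    )


def smooth_bias_field(shape, strength: float = 0.3) -> np.ndarray:
    """Deterministic smooth multiplicative coil-bias surrogate.

    A broad Gaussian sensitivity bump toward one image corner, scaled so the
    field spans roughly ``1 +- strength`` and stays strictly positive.
    """
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    sigma = max(shape) * 0.8
    bump = np.exp(-((rows - 0) ** 2 + (cols - 0) ** 2) / (2 * sigma**2))
    bump = (bump - bump.min()) / max(np.ptp(bump), 1e-12)
    return 1.0 + strength * (2 * bump - 1.0) * 0.5


def _unit_tissue_curve(spec: PhantomSpec, aif_full: np.ndarray) -> np.ndarray:
    """Tissue enhancement curve of a pixel with true MBF = 1."""
    r_unit = np.exp(-spec.k * spec.tau0) + 1.0  # makes h(0) (delay-free) = 1
    params = FermiParams(R=r_unit, k=spec.k, tau0=spec.tau0, tau_d=spec.tau_d)
    return fermi_model_curve(aif_full, params, spec.dt)


def _noise_sigma(spec: PhantomSpec, c_unit: np.ndarray, fields: list) -> float:
    if spec.snr is not None:
        mean_mbf = np.nanmean([np.nanmean(f) for f in fields])
        return float(np.max(c_unit) * mean_mbf / spec.snr)
    return float(spec.noise_sigma)


def generate_perfusion_series(spec: PhantomSpec, state: str):
    """Generate the stress or rest series for every slice.

    Returns ``(series_list, aif, truth)`` where ``series_list`` holds one
    :class:`~fermiperf.preprocess.PerfusionSeries` per slice, ``aif`` is the
    clean low-dose arterial input curve and ``truth`` the subject's ground
    truth (with this state's jitter shifts recorded).
    """
    if state not in _STATE_STREAM:
        raise ValueError("state must be 'rest' or 'stress'")
    truth = phantom_truth(spec)
    rng = np.random.default_rng([spec.seed, _STATE_STREAM[state]])

    aif = generate_aif(spec.aif, spec.n_frames, spec.dt)
    aif_full = aif.values * spec.aif.dose_ratio
    c_unit = _unit_tissue_curve(spec, aif_full)
    fields = truth.mbf_rest if state == "rest" else truth.mbf_stress
    sigma = _noise_sigma(spec, c_unit, fields)
    bias = (
        smooth_bias_field(spec.shape, spec.bias_strength)
        if spec.bias_strength > 0
        else None
    )

    series_list = []
    shifts_all = []
    for i, contours in enumerate(truth.contours):
        annulus = contours.annulus_mask(spec.shape)
        blood = contours.endo_mask(spec.shape)
        mbf = np.where(annulus, fields[i], 0.0)
        mbf = np.nan_to_num(mbf, nan=0.0)

        frames = np.full((spec.n_frames,) + tuple(spec.shape), spec.baseline)
        frames += c_unit[:, None, None] * mbf[None, :, :]
        frames[:, blood] = spec.baseline + aif_full[:, None]
        if bias is not None:
            frames *= bias[None, :, :]
        if sigma > 0:
            frames = frames + rng.normal(0.0, sigma, frames.shape)

        shifts = np.zeros((spec.n_frames, 2), dtype=int)
        if spec.jitter_px > 0:
            shifts = rng.integers(
                -spec.jitter_px, spec.jitter_px + 1, size=(spec.n_frames, 2)
            )
            for f in range(spec.n_frames):
                frames[f] = np.roll(frames[f], tuple(shifts[f]), axis=(0, 1))
        shifts_all.append(shifts)

        series_list.append(
            PerfusionSeries(
                frames=frames,
                times=spec.times,
                slice_label=spec.slice_labels[i],
                state=state,
            )
        )
    truth.jitter_shifts[state] = shifts_all
    return series_list, aif, truth


def remote_roi(
    spec: PhantomSpec,
    contours: ContourSet,
    scar_mask: np.ndarray,
    center_angle: float | None = None,
    width: float = np.pi / 3,
) -> np.ndarray:
    """A remote (non-enhanced) reference sector, disjoint from scar.

    Defaults to the sector diametrically opposite the scar (or the sector at
    pi relative to the reference when there is no scar).
    """
    if center_angle is None:
        if spec.scar is not None:
            center_angle = (
                spec.scar.angle_start + spec.scar.angle_width / 2 + np.pi
            )
        else:
            center_angle = np.pi
    roi = region_mask(
        contours, spec.shape, center_angle - width / 2, width, (0.0, 1.0)
    )
    roi &= ~np.asarray(scar_mask, dtype=bool)
    if not roi.any():
        raise ValueError("remote ROI is empty; adjust its sector")
    return roi


def generate_lge_image(
    spec: PhantomSpec,
    slice_index: int = 0,
    at_means: bool = False,
    remote_angle: float | None = None,
):
    """Generate one slice's LGE image and its remote reference mask.

    Remote myocardium is Normal(mu, sd); scar pixels have mean
    ``mu + offset * sd``.  ``at_means`` suppresses the noise draw (every
    pixel at its mean), which is convenient for exact threshold checks.
    """
    truth = phantom_truth(spec)
    contours = truth.contours[slice_index]
    scar = truth.scar_masks[slice_index]
    annulus = contours.annulus_mask(spec.shape)
    blood = contours.endo_mask(spec.shape)
    rng = np.random.default_rng([spec.seed, _LGE_STREAM, slice_index])

    mu, sd = spec.lge_remote_mean, spec.lge_remote_sd
    image = np.full(spec.shape, 0.2 * mu)
    image[blood] = 0.5 * mu
    means = np.full(spec.shape, np.nan)
    means[annulus] = mu
    if spec.scar is not None:
        means[scar] = mu + spec.scar.lge_offset_sd * sd
        if spec.scar.rim_offset_sd is not None and scar.any():
            # graded epicardial rim near the detection threshold, so the
            # segmented extent depends (slightly) on the operator's remote
            # region choice, as it does clinically
            rows, cols = np.nonzero(scar)
            _, depth = contours.polar_coordinates(np.stack([rows, cols], axis=1))
            d0, d1 = spec.scar.depth_range
            rim = depth > d1 - spec.scar.rim_depth_frac * (d1 - d0)
            means[rows[rim], cols[rim]] = mu + spec.scar.rim_offset_sd * sd
    if at_means:
        image[annulus] = means[annulus]
    else:
        image[annulus] = rng.normal(means[annulus], sd)

    remote = remote_roi(spec, contours, scar, center_angle=remote_angle)
    return LGEImage(image=image, contours=contours, remote_mask=remote), remote


@dataclass
class SubjectPhantom:
    """Everything generated for one synthetic subject."""

    spec: PhantomSpec
    stress: list
    rest: list
    aif: Curve
    lge: list
    remote_masks: list
    truth: PhantomTruth

    @property
    def has_scar(self) -> bool:
        return any(m.any() for m in self.truth.scar_masks)


def generate_subject(spec: PhantomSpec) -> SubjectPhantom:
    """Generate both states plus per-slice LGE images for one subject."""
    stress, aif, truth = generate_perfusion_series(spec, "stress")
    rest, _, rest_truth = generate_perfusion_series(spec, "rest")
    truth.jitter_shifts.update(rest_truth.jitter_shifts)
    lge_images, remotes = [], []
    for i in range(spec.n_slices):
        img, remote = generate_lge_image(spec, slice_index=i)
        lge_images.append(img)
        remotes.append(remote)
    return SubjectPhantom(
        spec=spec,
        stress=stress,
        rest=rest,
        aif=aif,
        lge=lge_images,
        remote_masks=remotes,
        truth=truth,
    )


def correction_analysis_spec(
    shape=(64, 64),
    seed: int = 0,
    scar_fraction: float = 0.07,
    tail_fraction: float = 0.05,
    mpr_floor: float = 0.5,
    mpr_ceiling: float = 1.4,
    mpr_normal: float = 2.8,
    grid_step: float = 0.1,
    **overrides,
) -> PhantomSpec:
    """Single-slice phantom expressing the scar-correction regime.

    Scar pixels (a contiguous sector, ~``scar_fraction`` of the annulus) get
    apparent stress MPR drawn deterministically from a triangular density on
    [floor, ceiling] (mass concentrated toward the ceiling, i.e. a convex
    CDF); a small ``tail_fraction`` of non-scar pixels is uniformly spread
    over the same interval (mimicking noise-depressed normal pixels) and the
    rest of the myocardium sits at ``mpr_normal``, above any threshold of
    interest.  With rest MBF 1 everywhere, the stress field equals the MPR
    field.  Under these populations the scar MPR distribution stochastically
    dominates (from below) the non-scar one, so the scar-corrected burden
    can never exceed the uncorrected burden, and the relative-error curve
    rises monotonically up to the scar-MPR ceiling and is exactly flat
    beyond it.  Values are nudged away from multiples of ``grid_step`` so
    threshold comparisons are never borderline.
    """
    spec = PhantomSpec(
        shape=shape,
        slice_labels=("mid",),
        endo_radii_mm=(16.0,),
        epi_radii_mm=(25.0,),
        rest_mbf=1.0,
        stress_mbf=mpr_normal,
        scar=ScarSpec(
            angle_start=0.4,
            angle_width=2 * np.pi * scar_fraction,
            depth_range=(0.0, 1.0),
            slices=(0,),
            stress_mbf=mpr_floor,  # placeholder; field is overridden below
        ),
        seed=seed,
        **overrides,
    )
    contours = slice_contours(spec)[0]
    annulus = contours.annulus_mask(spec.shape)
    scar = scar_masks(spec)[0]

    def _nudge(values):
        offset = np.mod(values, grid_step)
        near = np.minimum(offset, grid_step - offset) < 1e-3
        return values + np.where(near, 2e-3, 0.0)

    span = mpr_ceiling - mpr_floor
    stress = np.full(spec.shape, np.nan)
    stress[annulus] = mpr_normal
    s_rows, s_cols = np.nonzero(scar)
    n_scar = s_rows.size
    u = (np.arange(n_scar) + 0.5) / n_scar
    stress[s_rows, s_cols] = _nudge(mpr_floor + span * np.sqrt(u))

    non_scar = annulus & ~scar
    n_rows, n_cols = np.nonzero(non_scar)
    n_tail = max(2, int(round(tail_fraction * annulus.sum())))
    step = max(1, n_rows.size // n_tail)
    sel = np.arange(0, n_rows.size, step)[:n_tail]
    v = (np.arange(sel.size) + 0.5) / sel.size
    stress[n_rows[sel], n_cols[sel]] = _nudge(mpr_floor + span * v)

    rest = np.full(spec.shape, np.nan)
    rest[annulus] = 1.0
    return dataclasses.replace(
        spec, stress_mbf_fields=(stress,), rest_mbf_fields=(rest,)
    )


def generate_cohort(
    n_subjects: int,
    lge_prevalence: float = 0.7,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list:
    """Per-subject phantom specs with cohort-level statistical structure.

    ``round(lge_prevalence * n_subjects)`` subjects (chosen by a seeded
    permutation) carry scar with depressed scar MPR (< 1) and a moderately
    hypoperfused peri-scar band, emulating larger ischemic burden in
    scar-positive subjects even after correction.  About 60 % of subjects
    additionally get an LGE-negative subendocardial stress defect.  Resting
    flow and hyperemic response vary subject to subject.

    Returns a list of :class:`PhantomSpec`; generate each with
    :func:`generate_subject`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= lge_prevalence <= 1:
        raise ValueError("lge_prevalence must be in [0, 1]")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    n_scar = int(round(lge_prevalence * n_subjects))
    scar_subjects = set(rng.permutation(n_subjects)[:n_scar].tolist())
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)

    specs = []
    for i in range(n_subjects):
        rest = float(np.clip(rng.normal(1.0, 0.10), 0.7, 1.3))
        stress = float(np.clip(rng.normal(3.0, 0.35), 2.0, 4.2))
        defect = None
        has_defect = rng.random() < (0.8 if i in scar_subjects else 0.5)
        if has_defect:
            defect = RegionSpec(
                angle_start=float(rng.uniform(0, 2 * np.pi)),
                angle_width=float(rng.uniform(np.pi / 4, np.pi / 2)),
                depth_range=(0.0, float(rng.uniform(0.4, 0.6))),
                slices=(0, 1, 2),
                stress_mbf=rest * float(rng.uniform(1.2, 1.5)),
            )
        scar = None
        if i in scar_subjects:
            scar = ScarSpec(
                angle_start=float(rng.uniform(0, 2 * np.pi)),
                angle_width=float(rng.uniform(np.pi / 6, np.pi / 2)),
                depth_range=(0.2, 0.8),
                slices=(0, 1),
                stress_mbf=rest * float(rng.uniform(0.5, 0.9)),
                lge_offset_sd=10.0,
                peri_angle=0.35,
                peri_stress_mbf=rest * 1.3,
                rim_offset_sd=6.5,
            )
        specs.append(
            dataclasses.replace(
                base,
                rest_mbf=rest,
                stress_mbf=stress,
                defect=defect,
                scar=scar,
                seed=int(child_seeds[i]),
            )
        )
    return specs
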