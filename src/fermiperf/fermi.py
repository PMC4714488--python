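"""Fermi-constrained deconvolution of first-pass perfusion signal curves.

The tissue impulse response of a myocardial region is modelled by the Fermi
function

    h(t) = R * [1 / (exp((t - tau0 - tau_d) * k) + 1)] * u(t - tau_d)

where ``R`` is the contrast-influx amplitude, ``k`` the washout decay rate of
``h``, ``tau0`` the width of the initial shoulder during which little contrast
has left the region, ``tau_d`` the bolus-arrival delay between the arterial
input (LV blood pool) and the tissue, and ``u`` the unit step.  The measured
tissue enhancement curve is the causal convolution of the arterial input
function (AIF) with ``h``.  Myocardial blood flow (MBF) is the initial height
of the impulse response; because the unit step would force a literal ``h(0)``
to zero whenever ``tau_d > 0``, MBF is evaluated with the delay removed:

    MBF = R / (exp(-tau0 * k) + 1)

Fitting minimises the sum of squared differences between the measured tissue
curve and ``(aif * h) * dt`` over ``(R, k, tau0)`` with ``tau_d`` held fixed;
the delay itself is chosen by an exhaustive search over integer-frame
candidates (:func:`estimate_delay`).

The fit is exposed both as a scikit-learn style estimator
(:class:`FermiDeconvolution`) and as the plain function :func:`fit_fermi`.
Nominal flow units are mL/g/min under the linear signal-concentration
assumption of a dual-bolus acquisition; all recovery guarantees in the test
suite are relative, not absolute.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "Curve",
    "FermiParams",
    "FitResult",
    "MBFMap",
    "MPRMap",
    "fermi_impulse_response",
    "fermi_model_curve",
    "FermiDeconvolution",
    "fit_fermi",
    "estimate_delay",
    "baseline_correct",
    "quantify_segmental",
    "quantify_pixelwise",
    "compute_mpr",
]

#: default box bounds on (R, k, tau0) for the constrained fit
DEFAULT_BOUNDS = ((1e-8, 1e-4, 0.0), (100.0, 10.0, 60.0))


@dataclass(frozen=True)
class Curve:
    """A uniformly sampled signal-time curve."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError("curve contains non-finite samples")
        if times.size >= 2:
            steps = np.diff(times)
            dt = steps.mean()
            if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * abs(dt)):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need at least two samples to define dt")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FermiParams:
    """Parameters of the Fermi impulse response."""

    R: float
    k: float
    tau0: float
    tau_d: float = 0.0

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.tau0 < 0:
            raise ValueError(f"tau0 must be >= 0, got {self.tau0}")
        if self.tau_d < 0:
            raise ValueError(f"tau_d must be >= 0, got {self.tau_d}")

    @property
    def mbf(self) -> float:
        """Initial height of the delay-free impulse response."""
        return self.R / (np.exp(-self.tau0 * self.k) + 1.0)


def fermi_impulse_response(params: FermiParams, t) -> np.ndarray:
    """Evaluate the Fermi impulse response at times ``t`` (seconds).

    Zero for ``t < tau_d``; ``R / (exp((t - tau0 - tau_d) k) + 1)`` otherwise.
    At ``t = tau0 + tau_d`` the value is exactly ``R / 2``.
    """
    t = np.asarray(t, dtype=float)
    x = (t - params.tau0 - params.tau_d) * params.k
    # clip the exponent to avoid overflow; the response underflows to 0 anyway
    h = params.R / (np.exp(np.clip(x, -700.0, 700.0)) + 1.0)
    return np.where(t < params.tau_d, 0.0, h)


def fermi_model_curve(aif: np.ndarray, params: FermiParams, dt: float) -> np.ndarray:
    """Causal discrete convolution ``(aif * h) * dt`` on the AIF's grid.

    Rectangle-rule discretisation with step ``dt``, matching a
    one-sample-per-heartbeat acquisition.
    """
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    t = np.arange(n) * dt
    h = fermi_impulse_response(params, t)
    return np.convolve(aif, h)[:n] * dt


@dataclass
class FitResult:
    """Outcome of a single Fermi deconvolution fit."""

    params: FermiParams | None
    mbf: float
    rss: float
    converged: bool
    n_iter: int
    tau_d: float

    @property
    def valid(self) -> bool:
        return self.converged and np.isfinite(self.mbf) and self.mbf > 0


class FermiDeconvolution(BaseEstimator):
    """Fermi-constrained deconvolution as a scikit-learn style estimator.

    Parameters
    ----------
    dt : float
        Sampling interval of both curves (seconds per frame / heartbeat).
    tau_d : float
        Bolus-arrival delay, held fixed during the fit (seconds).
    baseline_frames : int
        Number of initial pre-contrast frames whose mean is subtracted from
        the tissue curve before fitting.  0 means the curve is already
        baseline-corrected.
    k_init, tau0_init : float
        Initial guesses for the washout rate (1/s) and shoulder width (s).
        The amplitude ``R`` is initialised from the ratio of the tissue peak
        to the peak of the running AIF integral.
    bounds : pair of 3-tuples
        Lower and upper box bounds on (R, k, tau0).
    tol : float
        Termination tolerance on the residual change.
    max_iter : int
        Maximum number of objective evaluations.

    Attributes
    ----------
    R_, k_, tau0_ : float
        Fitted Fermi parameters.
    mbf_ : float
        Myocardial blood flow, ``R_ / (exp(-tau0_ * k_) + 1)``; NaN when the
        fit did not converge or the tissue curve was degenerate.
    rss_ : float
        Residual sum of squares at the solution.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        dt: float = 1.0,
        tau_d: float = 0.0,
        baseline_frames: int = 0,
        k_init: float = 0.1,
        tau0_init: float = 5.0,
        bounds=DEFAULT_BOUNDS,
        tol: float = 1e-12,
        max_iter: int = 500,
    ):
        self.dt = dt
        self.tau_d = tau_d
        self.baseline_frames = baseline_frames
        self.k_init = k_init
        self.tau0_init = tau0_init
        self.bounds = bounds
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, aif, tissue):
        """Fit the Fermi model to a tissue curve given the arterial input.

        Parameters
        ----------
        aif : array-like
            Arterial input samples on the common uniform grid (already scaled
            to full dose for dual-bolus data).
        tissue : array-like
            Tissue signal samples on the same grid.
        """
        aif = np.asarray(aif, dtype=float)
        tissue = np.asarray(tissue, dtype=float)
        if aif.ndim != 1 or aif.shape != tissue.shape:
            raise ValueError("aif and tissue must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(aif)) and np.all(np.isfinite(tissue))):
            raise ValueError("curves contain non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

        y = tissue.copy()
        if self.baseline_frames > 0:
            y = y - y[: self.baseline_frames].mean()

        self.aif_ = aif
        self.tissue_ = y
        self.tau_d_ = float(self.tau_d)

        if np.max(np.abs(y)) == 0.0 or np.max(np.abs(aif)) == 0.0:
            # degenerate input: report an invalid result, never raise
            self._set_invalid()
            return self

        lb, ub = self.bounds
        n = aif.size
        t = np.arange(n) * self.dt
        running_integral = np.cumsum(aif) * self.dt
        peak_int = np.max(running_integral)
        r0 = np.max(y) / peak_int if peak_int > 0 else 1.0
        x0 = np.clip(
            [r0, self.k_init, self.tau0_init],
            np.asarray(lb) * (1 + 1e-9),
            np.asarray(ub) * (1 - 1e-9),
        )

        def residuals(x):
            params = _raw_params(x[0], x[1], x[2], self.tau_d_)
            h = _raw_impulse(params, t)
            return np.convolve(aif, h)[:n] * self.dt - y

        res = least_squares(
            residuals,
            x0,
            bounds=(lb, ub),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=None,
            max_nfev=self.max_iter * 4,
        )

        self.n_iter_ = int(res.nfev)
        self.converged_ = bool(res.status > 0)
        self.rss_ = float(2.0 * res.cost)
        if self.converged_:
            self.R_, self.k_, self.tau0_ = (float(v) for v in res.x)
            self.params_ = FermiParams(self.R_, self.k_, self.tau0_, self.tau_d_)
            self.mbf_ = self.params_.mbf
        else:
            self._set_invalid()
        return self

    def _set_invalid(self):
        self.R_ = self.k_ = self.tau0_ = np.nan
        self.params_ = None
        self.mbf_ = np.nan
        self.converged_ = False
        self.rss_ = np.nan
        self.n_iter_ = 0

    def predict(self, aif=None) -> np.ndarray:
        """Model tissue curve for an AIF (default: the one used in fit)."""
        if not hasattr(self, "converged_"):
            raise AttributeError("estimator is not fitted")
        if self.params_ is None:
            raise ValueError("fit did not converge; no model curve available")
        aif = self.aif_ if aif is None else np.asarray(aif, dtype=float)
        return fermi_model_curve(aif, self.params_, self.dt)

    def result_(self) -> FitResult:
        """The fit packaged as a :class:`FitResult`."""
        return FitResult(
            params=self.params_,
            mbf=self.mbf_,
            rss=self.rss_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            tau_d=self.tau_d_,
        )


def _raw_params(R, k, tau0, tau_d):
    # bypass FermiParams validation inside the optimiser hot loop
    p = FermiParams.__new__(FermiParams)
    object.__setattr__(p, "R", R)
    object.__setattr__(p, "k", k)
    object.__setattr__(p, "tau0", tau0)
    object.__setattr__(p, "tau_d", tau_d)
    return p


def _raw_impulse(params, t):
    x = (t - params.tau0 - params.tau_d) * params.k
    h = params.R / (np.exp(np.clip(x, -700.0, 700.0)) + 1.0)
    return np.where(t < params.tau_d, 0.0, h)


def fit_fermi(
    aif,
    tissue,
    dt: float,
    tau_d: float = 0.0,
    baseline_frames: int = 0,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`FermiDeconvolution`.

    ``tissue`` may be raw signal (set ``baseline_frames``) or already
    baseline-corrected enhancement.
    """
    est = FermiDeconvolution(
        dt=dt, tau_d=tau_d, baseline_frames=baseline_frames, **kwargs
    )
    est.fit(aif, tissue)
    return est.result_()


def baseline_correct(values: np.ndarray, n_frames: int = 3) -> np.ndarray:
    """Subtract the mean of the first ``n_frames`` pre-contrast samples."""
    values = np.asarray(values, dtype=float)
    if n_frames <= 0:
        return values.copy()
    return values - values[..., :n_frames].mean(axis=-1, keepdims=True)


def estimate_delay(
    aif,
    tissue,
    dt: float,
    candidates=range(6),
    baseline_frames: int = 0,
    **fit_kwargs,
) -> float:
    """Choose the bolus-arrival delay by exhaustive search.

    Runs a trial fit for each candidate delay (integer number of frames) and
    returns the delay, in seconds, that minimises the residual sum of squares.
    Ties are broken toward the smallest delay.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate delay list is empty")
    best_tau, best_rss = None, np.inf
    for frames in candidates:
        result = fit_fermi(
            aif,
            tissue,
            dt,
            tau_d=frames * dt,
            baseline_frames=baseline_frames,
            **fit_kwargs,
        )
        rss = result.rss if result.valid else np.inf
        if rss < best_rss:
            best_rss, best_tau = rss, frames * dt
    if best_tau is None:
        # every trial fit failed; fall back to zero delay
        warnings.warn("delay estimation failed for all candidates; using 0")
        return 0.0
    return float(best_tau)


@dataclass
class MBFMap:
    """Per-pixel myocardial blood flow map for one slice and one state."""

    values: np.ndarray
    valid: np.ndarray
    state: str
    slice_label: str
    tau_d: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class MPRMap:
    """Per-pixel myocardial perfusion reserve (stress MBF / rest MBF)."""

    values: np.ndarray
    valid: np.ndarray
    slice_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")


def _mean_myocardial_curve(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return frames[:, mask].mean(axis=1)


def quantify_pixelwise(
    series,
    mask: np.ndarray,
    aif: Curve,
    tau_d: float | None = None,
    baseline_frames: int = 3,
    dose_ratio: float = 1.0,
    delay_candidates=range(6),
    exclude: np.ndarray | None = None,
    **fit_kwargs,
) -> MBFMap:
    """Fit the Fermi model to every myocardial pixel's time course.

    The delay ``tau_d`` is shared across pixels; when not given it is
    estimated once from the mean myocardial curve.  Failed or degenerate fits
    are flagged in the validity mask, never interpolated.  ``exclude`` marks
    pixels (e.g. dark-rim artifact regions) to leave out of the map entirely.

    Returns an :class:`MBFMap` on the series' pixel grid.
    """
    frames = series.frames
    mask = np.asarray(mask, dtype=bool)
    if exclude is not None:
        mask = mask & ~np.asarray(exclude, dtype=bool)
    if not mask.any():
        raise ValueError("myocardial mask is empty")
    dt = series.dt
    aif_values = np.asarray(aif.values, dtype=float) * dose_ratio

    if tau_d is None:
        mean_curve = baseline_correct(
            _mean_myocardial_curve(frames, mask), baseline_frames
        )
        tau_d = estimate_delay(aif_values, mean_curve, dt, delay_candidates, **fit_kwargs)

    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    est = FermiDeconvolution(dt=dt, tau_d=tau_d, baseline_frames=0, **fit_kwargs)
    rows, cols = np.nonzero(mask)
    curves = baseline_correct(frames[:, rows, cols].T, baseline_frames)
    for i in range(rows.size):
        est.fit(aif_values, curves[i])
        if est.converged_ and np.isfinite(est.mbf_) and est.mbf_ > 0:
            values[rows[i], cols[i]] = est.mbf_
            valid[rows[i], cols[i]] = True
    return MBFMap(
        values=values,
        valid=valid,
        state=series.state,
        slice_label=series.slice_label,
        tau_d=tau_d,
    )


def quantify_segmental(
    series,
    segments,
    aif: Curve,
    tau_d: float | None = None,
    baseline_frames: int = 3,
    dose_ratio: float = 1.0,
    delay_candidates=range(6),
    **fit_kwargs,
) -> pd.DataFrame:
    """Segmental MBF from spatially averaged signal curves.

    For each segment the pixel time courses are averaged, baseline-corrected
    and deconvolved.  Returns a table with one row per segment (columns:
    segment, n_pixels, mbf, R, k, tau0, tau_d, rss, converged); empty segments
    produce an invalid row.
    """
    frames = series.frames
    labels = segments.labels
    dt = series.dt
    aif_values = np.asarray(aif.values, dtype=float) * dose_ratio

    myo = labels > 0
    if tau_d is None and myo.any():
        mean_curve = baseline_correct(
            _mean_myocardial_curve(frames, myo), baseline_frames
        )
        tau_d = estimate_delay(aif_values, mean_curve, dt, delay_candidates, **fit_kwargs)
    tau_d = 0.0 if tau_d is None else tau_d

    rows = []
    for seg_id in segments.segment_ids:
        seg_mask = labels == seg_id
        n_px = int(seg_mask.sum())
        if n_px == 0:
            rows.append(
                dict(segment=seg_id, n_pixels=0, mbf=np.nan, R=np.nan, k=np.nan,
                     tau0=np.nan, tau_d=tau_d, rss=np.nan, converged=False)
            )
            continue
        curve = baseline_correct(
            _mean_myocardial_curve(frames, seg_mask), baseline_frames
        )
        result = fit_fermi(aif_values, curve, dt, tau_d=tau_d, **fit_kwargs)
        p = result.params
        rows.append(
            dict(
                segment=seg_id,
                n_pixels=n_px,
                mbf=result.mbf if result.valid else np.nan,
                R=p.R if p else np.nan,
                k=p.k if p else np.nan,
                tau0=p.tau0 if p else np.nan,
                tau_d=tau_d,
                rss=result.rss,
                converged=result.valid,
            )
        )
    return pd.DataFrame(rows)


def compute_mpr(stress: MBFMap, rest: MBFMap) -> MPRMap:
    """Pixelwise perfusion reserve: stress MBF / rest MBF.

    A pixel is valid only where both inputs are valid and rest MBF is
    strictly positive.
    """
    if stress.values.shape != rest.values.shape:
        raise ValueError("stress and rest maps have different geometry")
    valid = stress.valid & rest.valid & (rest.values > 0)
    values = np.full(stress.values.shape, np.nan)
    values[valid] = stress.values[valid] / rest.values[valid]
    return MPRMap(values=values, valid=valid, slice_label=stress.slice_label)
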