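"""ROI-level temporal preprocessing for resting-state BOLD series.

The cleaning chain operates on region-of-interest (ROI) time series already
extracted from volumetric data: linear detrending, an ideal (rectangular
FFT-domain) band-pass filter, ordinary-least-squares nuisance regression
(24-parameter motion expansion plus tissue signals supplied as columns), and
motion scrubbing of high framewise-displacement frames by linear
interpolation.  Volume-space steps (slice timing, realignment, spatial
normalisation, smoothing) are outside this package's scope.

The canonical order, mirroring common resting-state pipelines, is
detrend -> band-pass -> nuisance regression -> scrubbing; see
:func:`clean_subject`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

logger = logging.getLogger("fcgraph")

#: Head radius (mm) used to convert rotation changes to arc displacement.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Framewise-displacement scrubbing threshold in mm.
DEFAULT_FD_THRESHOLD_MM = 0.5


@dataclass
class RoiTimeSeries:
    """One subject's frames x ROIs signal matrix with its sampling interval.

    Parameters
    ----------
    values
        Array of shape ``(n_frames, n_rois)`` in arbitrary BOLD units.
    tr
        Repetition time (sampling interval) in seconds.
    roi_ids
        Ordered, unique ROI labels, one per column.
    """

    values: np.ndarray
    tr: float
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D frames x ROIs array")
        if self.values.shape[0] < 2:
            raise ValueError("a time series needs at least 2 frames")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.values.shape[1])]
        if len(self.roi_ids) != self.values.shape[1]:
            raise ValueError("roi_ids length must match the number of columns")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("roi_ids must be unique")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: frames x 6.

    Columns are three translations (mm) followed by three rotations
    (radians).  Framewise displacement is derived on demand via
    :func:`framewise_displacement`.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must have exactly 6 columns")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace must have at least one frame")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class ScrubReport:
    """Outcome of motion scrubbing for one subject."""

    replaced_indices: list[int]
    fraction_replaced: float
    threshold: float


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove a per-ROI least-squares line (intercept + slope).

    Output columns have (numerically) zero mean and zero linear trend.
    """
    if ts.n_frames < 3:
        raise ValueError("linear detrending needs at least 3 frames")
    t = np.arange(ts.n_frames, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return replace(ts, values=ts.values - design @ coef)


def bandpass_ideal(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Ideal (rectangular) FFT-domain band-pass filter.

    Retains exactly the discrete frequency bins ``low_hz <= f <= high_hz``
    and zeroes every other bin, so pass-band sinusoids survive essentially
    unchanged and stop-band sinusoids are annihilated.  The DC bin is
    removed whenever ``low_hz > 0``.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds the Nyquist frequency {nyquist} Hz "
            f"for tr={ts.tr}s"
        )
    freqs = np.fft.rfftfreq(ts.n_frames, d=ts.tr)
    mask = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spectrum = np.fft.rfft(ts.values, axis=0)
    spectrum[~mask, :] = 0.0
    filtered = np.fft.irfft(spectrum, n=ts.n_frames, axis=0)
    return replace(ts, values=filtered)


def friston24_expansion(motion: MotionTrace) -> np.ndarray:
    """24-parameter motion regressor matrix.

    For each of the 6 rigid-body parameters ``p`` the expansion contributes
    ``[p, p^2, p_lag1, p_lag1^2]``; lagged values at frame 0 are set to 0.
    Column order is the 6 raw parameters, their squares, the 6 one-frame
    lags, then the squared lags.
    """
    p = motion.params
    lag = np.zeros_like(p)
    lag[1:] = p[:-1]
    return np.hstack([p, p**2, lag, lag**2])


def regress_nuisance(
    ts: RoiTimeSeries, regressors: np.ndarray
) -> RoiTimeSeries:
    """OLS-residualise every ROI on the given regressors (plus intercept).

    Rank-deficient designs are repaired by dropping linearly dependent
    columns (greedily, by QR pivoting) with a logged warning; residuals are
    orthogonal to every retained regressor.
    """
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != ts.n_frames:
        raise ValueError("regressor frame count must match the time series")
    design = np.column_stack([np.ones(ts.n_frames), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # keep a maximal independent subset, preferring earlier columns
        _, _, piv = scipy.linalg.qr(design, pivoting=True)
        keep = np.sort(piv[:rank])
        logger.warning(
            "rank-deficient nuisance design: dropping %d dependent column(s)",
            design.shape[1] - rank,
        )
        design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return replace(ts, values=ts.values - design @ coef)


def framewise_displacement(
    motion: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement in mm.

    ``FD_t = sum |delta translation| + r * sum |delta rotation|`` with
    rotations in radians projected onto a sphere of radius
    ``head_radius_mm``; ``FD_0 = 0`` by convention.
    """
    if motion.n_frames < 2:
        raise ValueError("framewise displacement needs at least 2 frames")
    diff = np.abs(np.diff(motion.params, axis=0))
    fd = np.zeros(motion.n_frames)
    fd[1:] = diff[:, :3].sum(axis=1) + head_radius_mm * diff[:, 3:].sum(axis=1)
    return fd


def scrub_interpolate(
    ts: RoiTimeSeries,
    fd: np.ndarray,
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
) -> tuple[RoiTimeSeries, ScrubReport]:
    """Replace frames with ``FD > threshold`` by linear interpolation.

    Interpolation is per-ROI between the nearest retained frames; leading or
    trailing bad frames are copied from the nearest retained frame.  The
    report lists the replaced frame indices and their fraction.

    Raises
    ------
    ValueError
        If every frame exceeds the threshold (the subject should be excluded
        rather than fabricated wholesale).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != ts.n_frames:
        raise ValueError("fd length must match the number of frames")
    bad = fd > threshold
    if bad.all():
        raise ValueError(
            "all frames exceed the FD threshold; exclude this subject"
        )
    report = ScrubReport(
        replaced_indices=[int(i) for i in np.flatnonzero(bad)],
        fraction_replaced=float(bad.mean()),
        threshold=float(threshold),
    )
    if not bad.any():
        return replace(ts, values=ts.values.copy()), report
    good_idx = np.flatnonzero(~bad)
    frames = np.arange(ts.n_frames)
    values = ts.values.copy()
    for j in range(ts.n_rois):
        # np.interp clamps outside the good range = copy nearest retained
        values[bad, j] = np.interp(frames[bad], good_idx, ts.values[good_idx, j])
    return replace(ts, values=values), report


def exceeds_motion_limit(
    motion: MotionTrace, max_trans_mm: float = 2.0, max_rot_deg: float = 2.0
) -> bool:
    """Cohort-level exclusion flag: translation > 2 mm or rotation > 2 deg.

    Mirrors the common head-motion exclusion rule applied before any
    subject enters group analysis.
    """
    trans_ok = np.abs(motion.params[:, :3]).max() <= max_trans_mm
    rot_ok = np.abs(np.degrees(motion.params[:, 3:])).max() <= max_rot_deg
    return not (trans_ok and rot_ok)


def clean_subject(
    ts: RoiTimeSeries,
    motion: MotionTrace | None = None,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    do_detrend: bool = True,
    do_bandpass: bool = True,
    do_regress: bool = True,
    do_scrub: bool = True,
) -> tuple[RoiTimeSeries, ScrubReport | None]:
    """Full cleaning chain in the fixed order detrend -> band-pass ->
    nuisance regression -> scrubbing.

    ``nuisance`` carries externally supplied columns (global / white-matter /
    CSF surrogates); motion regressors are expanded to the 24-parameter set
    internally when a motion trace is given.  Frame and ROI counts are never
    changed.
    """
    logger.info(
        "cleaning order: detrend=%s bandpass=%s regress=%s scrub=%s",
        do_detrend, do_bandpass, do_regress, do_scrub,
    )
    out = ts
    if do_detrend:
        out = detrend_linear(out)
    if do_bandpass:
        out = bandpass_ideal(out, low_hz, high_hz)
    if do_regress:
        cols = []
        if motion is not None:
            cols.append(friston24_expansion(motion))
        if nuisance is not None:
            cols.append(np.asarray(nuisance, dtype=float))
        if cols:
            out = regress_nuisance(out, np.hstack(cols))
    report: ScrubReport | None = None
    if do_scrub and motion is not None:
        fd = framewise_displacement(motion)
        out, report = scrub_interpolate(out, fd, fd_threshold)
        if report.replaced_indices:
            logger.info(
                "scrubbed %d frame(s) (%.1f%%)",
                len(report.replaced_indices),
                100 * report.fraction_replaced,
            )
    return out, report
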