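"""fNIRS preprocessing: raw light intensity to standardized total hemoglobin.

The chain follows a fixed order — trim/concatenate by condition, channel
quality control, bandpass filtering, PCA motion correction, Modified
Beer-Lambert conversion, z-scored total hemoglobin — and each applied step is
recorded in the output's provenance.  Quality control only flags channels; it
never modifies data.

Channel QC implements two rules: a channel is unusable if detector saturation
lasts for more than ``max_saturation_s`` seconds (default 2 s), or if its
power spectrum resembles white noise, operationalized as a quartile
coefficient of dispersion of the PSD values below ``qcod_threshold``
(default 0.1).  The PSD is a one-sided averaged periodogram (Welch) with the
DC bin excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import DEFAULT_EXTINCTION, OpticalGeometry
from .types import (
    ChannelQCReport,
    DegenerateInputError,
    EmptyConditionError,
    HemoTimecourse,
    InvalidBandError,
    InvalidEventsError,
    InvalidGeometryError,
    InvalidSpecError,
    NoUsableChannelsError,
    RawIntensity,
)

__all__ = [
    "qc_channels",
    "qcod",
    "trim_concatenate",
    "bandpass",
    "pca_motion_correct",
    "mbll",
    "optical_density",
    "total_hb_signal",
    "preprocess_raw",
]


# --------------------------------------------------------------------------
# channel quality control
# --------------------------------------------------------------------------


def qcod(values: np.ndarray) -> float:
    """Quartile coefficient of dispersion, (Q3 - Q1) / (Q3 + Q1)."""
    q1, q3 = np.percentile(values, [25, 75])
    denom = q3 + q1
    if denom == 0:
        return 0.0
    return float((q3 - q1) / denom)


def _max_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def qc_channels(
    raw: RawIntensity,
    saturation_level: float | None = None,
    max_saturation_s: float = 2.0,
    qcod_threshold: float = 0.1,
    saturation_fraction: float = 0.99,
) -> ChannelQCReport:
    """Flag unusable channels by the saturation and white-noise rules.

    ``saturation_level`` defaults to ``saturation_fraction`` of the recording's
    ADC ceiling when one is declared; with neither, the saturation rule is
    skipped.  A channel is unusable if samples at/above that level (at either
    wavelength) run contiguously for strictly more than ``max_saturation_s``
    seconds, or if the QCoD of its PSD falls below ``qcod_threshold``.
    """
    fs = raw.sampling_rate
    if saturation_level is None and raw.adc_ceiling is not None:
        saturation_level = saturation_fraction * raw.adc_ceiling
    n_ch = raw.n_channels
    usable = np.ones(n_ch, dtype=bool)
    reasons: list[str] = []
    qcods = np.empty(n_ch)
    sat_runs = np.empty(n_ch)
    for ch in range(n_ch):
        x = raw.intensity[:, ch, :]  # (2, T)
        if saturation_level is not None:
            run = max(_max_run(x[w] >= saturation_level) for w in range(2))
        else:
            run = 0
        sat_runs[ch] = run / fs
        # Heavily averaged periodogram (short boxcar segments): a flat,
        # white-noise-like spectrum then shows very low dispersion across
        # frequency bins, while structured (hemodynamic or oscillatory)
        # signals spread power unevenly and score high.  DC bin excluded.
        nper = max(16, min(32, x.shape[1] // 8))
        ch_qcods = []
        for w in range(2):
            f, psd = sps.welch(x[w], fs=fs, nperseg=nper, window="boxcar")
            ch_qcods.append(qcod(psd[f > 0]))
        qcods[ch] = min(ch_qcods)
        if sat_runs[ch] > max_saturation_s:
            usable[ch] = False
            reasons.append("saturation")
        elif qcods[ch] < qcod_threshold:
            usable[ch] = False
            reasons.append("white_noise")
        else:
            reasons.append("ok")
    return ChannelQCReport(
        channel_ids=list(raw.channel_ids),
        usable=usable,
        reason=reasons,
        qcod=qcods,
        max_saturation_run_s=sat_runs,
    )


# --------------------------------------------------------------------------
# trimming / concatenation
# --------------------------------------------------------------------------


def trim_concatenate(
    recording: np.ndarray,
    events: pd.DataFrame,
    condition: str,
    sampling_rate: float,
) -> np.ndarray:
    """Extract event segments of one condition and concatenate them in order.

    ``events`` needs columns ``onset_s``, ``duration_s``, ``condition``.
    Output length is the sum of segment lengths.
    """
    recording = np.atleast_2d(np.asarray(recording, dtype=float))
    T = recording.shape[-1]
    sel = events[events["condition"] == condition]
    if len(sel) == 0:
        raise EmptyConditionError(f"no events with condition {condition!r}")
    pieces = []
    for _, ev in sel.iterrows():
        i0 = int(round(ev["onset_s"] * sampling_rate))
        n = int(round(ev["duration_s"] * sampling_rate))
        if i0 < 0 or i0 + n > T:
            raise InvalidEventsError(
                f"event at {ev['onset_s']}s (+{ev['duration_s']}s) is outside "
                f"the {T}-sample recording"
            )
        pieces.append(recording[:, i0 : i0 + n])
    return np.concatenate(pieces, axis=-1)


# --------------------------------------------------------------------------
# filtering and motion correction
# --------------------------------------------------------------------------


def bandpass(
    ts: np.ndarray,
    low: float = 0.005,
    high: float = 0.5,
    sampling_rate: float = 7.8,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis."""
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise InvalidBandError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq} Hz"
        )
    sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


def pca_motion_correct(ts: np.ndarray, variance_fraction: float = 0.8) -> np.ndarray:
    """Remove leading principal components of the channel x time matrix.

    Components are removed in decreasing-variance order until the removed set
    first reaches ``variance_fraction`` of total variance (capped at
    ``n_channels - 1`` components).  ``variance_fraction = 0`` removes
    nothing.  Motion artifacts shared across channels concentrate in the
    leading components, so this attenuates them while sparing channel-specific
    signal.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if not (0 <= variance_fraction < 1):
        raise InvalidSpecError("variance_fraction must be in [0, 1)")
    n_ch = ts.shape[0]
    if n_ch < 2:
        warnings.warn("PCA motion correction needs >= 2 channels; returning input")
        return ts.copy()
    if variance_fraction == 0:
        return ts.copy()
    mean = ts.mean(axis=1, keepdims=True)
    X = ts - mean
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_fraction) + 1)
    k = min(k, n_ch - 1)
    removed = (U[:, :k] * s[:k]) @ Vt[:k]
    return ts - removed


# --------------------------------------------------------------------------
# Modified Beer-Lambert Law
# --------------------------------------------------------------------------


def optical_density(
    raw: RawIntensity, baseline: np.ndarray | None = None
) -> np.ndarray:
    """Change in optical density, ``-log10(I / I0)``, shape (2, n_ch, T).

    Nonpositive intensity samples are flagged as missing (NaN) and excluded
    from the per-channel baseline mean.
    """
    I = raw.intensity
    bad = ~(I > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} nonpositive intensity samples flagged missing")
    I = np.where(bad, np.nan, I)
    if baseline is None:
        if raw.baseline_intensity is not None:
            baseline = np.asarray(raw.baseline_intensity, dtype=float)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                baseline = np.nanmean(I, axis=-1)
    if np.any(~(baseline > 0)):
        raise InvalidSpecError("baseline intensity must be positive")
    return -np.log10(I / baseline[:, :, None])


def _concentrations_from_od(
    od: np.ndarray,
    distance_cm: float,
    dpf: tuple[float, float],
    extinction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    E = np.asarray(extinction, dtype=float)
    if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12 * np.abs(E).max() ** 2:
        raise InvalidGeometryError("extinction matrix is singular or malformed")
    pathlength = distance_cm * np.asarray(dpf, dtype=float)
    od_per_path = od / pathlength[:, None, None]
    Einv = np.linalg.inv(E)
    conc = np.einsum("cw,wnt->cnt", Einv, od_per_path)
    return conc[0], conc[1]


def mbll(
    raw: RawIntensity,
    distance_cm: float = 3.0,
    dpf: tuple[float, float] = (6.0, 6.0),
    extinction: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the Modified Beer-Lambert Law: intensities -> (dHbO, dHbR).

    The baseline is each channel/wavelength's temporal mean unless the
    recording declares one (or ``baseline`` is passed).  Per time point the
    2x2 extinction system is solved with pathlength ``distance * DPF``.
    """
    od = optical_density(raw, baseline=baseline)
    if extinction is None:
        extinction = DEFAULT_EXTINCTION
    return _concentrations_from_od(od, distance_cm, dpf, extinction)


# --------------------------------------------------------------------------
# total hemoglobin
# --------------------------------------------------------------------------


def total_hb_signal(hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
    """Per-channel z-scored (HbO - HbR) signal; degenerate channels -> NaN.

    A channel whose HbO - HbR difference is constant carries no signal to
    standardize; it is excluded (NaN row) with a warning, and an error is
    raised if every channel is degenerate.
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    if hbo.shape != hbr.shape:
        raise InvalidSpecError("hbo and hbr must have the same shape")
    diff = hbo - hbr
    mean = np.nanmean(diff, axis=-1, keepdims=True)
    sd = np.nanstd(diff, axis=-1, keepdims=True)
    degenerate = (sd == 0).ravel()
    if degenerate.all():
        raise DegenerateInputError("all channels have constant HbO - HbR")
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) with constant HbO - HbR excluded"
        )
    sd = np.where(sd == 0, np.nan, sd)
    return (diff - mean) / sd


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------

PIPELINE_ORDER = [
    "trim_concatenate",
    "qc_channels",
    "bandpass",
    "pca_motion_correct",
    "mbll",
    "total_hb_zscore",
]


def preprocess_raw(
    raw: RawIntensity,
    events: pd.DataFrame | None = None,
    condition: str | None = None,
    low: float = 0.005,
    high: float = 0.5,
    pca_variance_fraction: float = 0.8,
    distance_cm: float = 3.0,
    dpf: tuple[float, float] = (6.0, 6.0),
    extinction: np.ndarray | None = None,
    saturation_level: float | None = None,
    max_saturation_s: float = 2.0,
    qcod_threshold: float = 0.1,
) -> tuple[HemoTimecourse, ChannelQCReport]:
    """Run the fixed preprocessing chain on one raw recording.

    Order: trim/concatenate (when events are given) -> QC -> bandpass (on
    optical density) -> PCA motion correction -> MBLL -> z-scored total.
    The chain is deterministic and never mutates ``raw``.
    """
    provenance: list[str] = []
    work = raw
    if events is not None:
        if condition is None:
            raise InvalidSpecError("condition is required when events are given")
        trimmed = np.stack(
            [
                trim_concatenate(work.intensity[w], events, condition, work.sampling_rate)
                for w in range(2)
            ]
        )
        work = RawIntensity(
            wavelengths=work.wavelengths,
            intensity=trimmed,
            sampling_rate=work.sampling_rate,
            channel_ids=list(work.channel_ids),
            adc_ceiling=work.adc_ceiling,
            baseline_intensity=work.baseline_intensity,
        )
        provenance.append("trim_concatenate")

    report = qc_channels(
        work,
        saturation_level=saturation_level,
        max_saturation_s=max_saturation_s,
        qcod_threshold=qcod_threshold,
    )
    provenance.append("qc_channels")
    if report.n_usable == 0:
        raise NoUsableChannelsError("quality control left no usable channels")

    od = optical_density(work)
    od = bandpass(od, low=low, high=high, sampling_rate=work.sampling_rate)
    provenance.append("bandpass")

    # motion correction across usable channels, per wavelength
    usable = report.usable
    for w in range(2):
        if usable.sum() >= 2:
            od[w, usable] = pca_motion_correct(od[w, usable], pca_variance_fraction)
    provenance.append("pca_motion_correct")

    hbo, hbr = _concentrations_from_od(
        od,
        distance_cm,
        dpf,
        DEFAULT_EXTINCTION if extinction is None else extinction,
    )
    provenance.append("mbll")

    hbo_u = np.where(usable[:, None], hbo, np.nan)
    hbr_u = np.where(usable[:, None], hbr, np.nan)
    total = total_hb_signal(hbo_u[usable], hbr_u[usable])
    full_total = np.full(hbo.shape, np.nan)
    full_total[usable] = total
    provenance.append("total_hb_zscore")

    tc = HemoTimecourse(
        hbo=hbo,
        hbr=hbr,
        total=full_total,
        sampling_rate=work.sampling_rate,
        channel_ids=list(work.channel_ids),
        provenance=provenance,
    )
    return tc, report
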