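"""Synthetic cohorts, raw optical recordings, and emotion-rating tables.

Every downstream stage of the pipeline (preprocessing, ISC, IS-RSA, the
two-part rating models) is exercised on data from this module, which encodes
the generative assumptions those analyses make:

* neural time courses follow the shared-response decomposition
  ``X_A(t) = alpha_A * C(t) + beta_A * id_A(t) + eps_A(t)`` with a stimulus-
  locked component ``C(t)`` common to all subjects, an idiosyncratic component
  ``id_A(t)`` and white noise;
* brain-behavior coupling can be injected with either an Anna-Karenina
  structure (high scorers synchronize, low scorers are idiosyncratic) or a
  Nearest-Neighbor structure (temporal similarity decays with the score gap);
* raw dual-wavelength light intensities are produced by the Beer-Lambert
  forward model so the MBLL inversion can be round-trip tested;
* discrete-emotion ratings come from a two-part (logistic + log-Gaussian)
  mixed model with subject random intercepts and exact boundary extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit
from scipy.stats import rankdata

from .types import Cohort, InvalidSpecError, RawIntensity

__all__ = [
    "SharedResponseSpec",
    "BehaviorCouplingSpec",
    "RatingsGenSpec",
    "OpticalGeometry",
    "simulate_shared_response",
    "simulate_coupled_cohort",
    "simulate_raw_intensity",
    "simulate_ratings",
    "DEFAULT_EXTINCTION",
]

NEGATIVE_EMOTIONS = ("anger", "disgust", "sadness")
POSITIVE_EMOTIONS = ("joy",)

# Molar extinction coefficients [cm^-1 / (mol/L)] at the two recording
# wavelengths, rows = (760 nm, 850 nm), columns = (HbO, HbR).  Standard
# tabulated values; overridable everywhere they are used.
DEFAULT_EXTINCTION = np.array(
    [
        [1486.5865, 3843.707],  # 760 nm
        [2526.391, 1798.643],  # 850 nm
    ]
)


# --------------------------------------------------------------------------
# shared-response cohorts
# --------------------------------------------------------------------------


@dataclass
class SharedResponseSpec:
    """Parameters of the shared-response cohort generator.

    ``shared_weights`` (alpha) and ``idio_weights`` (beta) may be scalars
    (broadcast over subjects) or per-subject arrays.  ``shared_signal_kind``
    selects the spectrum of the common signal ``C(t)``: ``smoothed-noise``
    is Gaussian noise low-pass filtered below 0.5 Hz (the hemodynamic band),
    ``band-limited`` restricts it to 0.01-0.2 Hz.  Both are standardized to
    unit sample variance.
    """

    n_subjects: int
    n_timepoints: int
    sampling_rate: float = 7.8
    shared_weights: float | np.ndarray = 1.0
    idio_weights: float | np.ndarray = 0.0
    noise_sd: float = 1.0
    shared_signal_kind: str = "smoothed-noise"
    n_channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise InvalidSpecError("n_subjects must be >= 2")
        if self.n_timepoints < 2:
            raise InvalidSpecError("n_timepoints must be >= 2")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be > 0")
        if self.shared_signal_kind not in ("smoothed-noise", "band-limited"):
            raise InvalidSpecError(
                f"unknown shared_signal_kind {self.shared_signal_kind!r}"
            )
        for name in ("shared_weights", "idio_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(w)):
                raise InvalidSpecError(f"{name} must be finite")
            if w.ndim == 1 and w.size != self.n_subjects:
                raise InvalidSpecError(f"{name} length must equal n_subjects")
            if w.ndim > 1:
                raise InvalidSpecError(f"{name} must be scalar or 1-D")

    def weight_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        alpha = np.broadcast_to(
            np.asarray(self.shared_weights, dtype=float), (self.n_subjects,)
        ).copy()
        beta = np.broadcast_to(
            np.asarray(self.idio_weights, dtype=float), (self.n_subjects,)
        ).copy()
        return alpha, beta


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _smooth_signal(
    rng: np.random.Generator, n: int, fs: float, kind: str, size: tuple = ()
) -> np.ndarray:
    """Unit-variance stationary signal(s) of length n with the requested band."""
    raw = rng.standard_normal(size + (n,))
    nyq = fs / 2.0
    if kind == "smoothed-noise":
        cut = 0.5
        if cut < nyq:
            sos = sps.butter(3, cut / nyq, btype="low", output="sos")
            raw = sps.sosfiltfilt(sos, raw, axis=-1)
    elif kind == "band-limited":
        lo, hi = 0.01, 0.2
        if hi < nyq:
            sos = sps.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
            raw = sps.sosfiltfilt(sos, raw, axis=-1)
    return _standardize(raw)


def simulate_shared_response(
    spec: SharedResponseSpec, _alpha_override: np.ndarray | None = None
) -> Cohort:
    """Simulate a cohort under the shared-response decomposition.

    The common signal C(t) is identical across subjects within one call
    (drawn once per channel); idiosyncratic signals and noise are independent
    across subjects.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    alpha, beta = spec.weight_arrays()
    if _alpha_override is not None:
        alpha = np.asarray(_alpha_override, dtype=float)
    n, T, n_ch = spec.n_subjects, spec.n_timepoints, spec.n_channels
    rng = np.random.default_rng(spec.seed)
    data = np.empty((n, n_ch, T))
    for ch in range(n_ch):
        c = _smooth_signal(rng, T, spec.sampling_rate, spec.shared_signal_kind)
        idio = _smooth_signal(
            rng, T, spec.sampling_rate, spec.shared_signal_kind, size=(n,)
        )
        eps = spec.noise_sd * rng.standard_normal((n, T))
        data[:, ch, :] = alpha[:, None] * c[None, :] + beta[:, None] * idio + eps
    subjects = [f"sub{i + 1:03d}" for i in range(n)]
    return Cohort(
        subjects=subjects,
        data=data,
        sampling_rate=spec.sampling_rate,
        seed=spec.seed,
    )


# --------------------------------------------------------------------------
# behavior-coupled cohorts
# --------------------------------------------------------------------------


@dataclass
class BehaviorCouplingSpec:
    """Cohort generator with brain-behavior coupling.

    ``structure='annak'`` makes a subject's shared-signal weight a monotone
    function of the rank of its behavioral score,
    ``alpha_A = base_alpha_A + kappa * (rank_A - 0.5) / n``: high scorers
    synchronize, low scorers stay idiosyncratic.  ``structure='nn'`` adds a
    latent Gaussian-process component along the score axis with correlation
    ``exp(-|score_i - score_j| / length_scale)``, so temporal similarity
    decays with the score gap.  ``kappa=0`` or ``structure='none'`` reduces
    exactly to the base shared-response cohort.
    """

    scores: np.ndarray
    structure: str
    coupling_strength: float
    base: SharedResponseSpec
    length_scale: float = 20.0

    def validate(self) -> None:
        self.base.validate()
        if self.structure not in ("annak", "nn", "none"):
            raise InvalidSpecError(f"unknown structure {self.structure!r}")
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size != self.base.n_subjects:
            raise InvalidSpecError("scores length must equal n_subjects")
        if not np.all(np.isfinite(scores)):
            raise InvalidSpecError("scores must be finite")
        if self.coupling_strength < 0:
            raise InvalidSpecError("coupling_strength (kappa) must be >= 0")
        if self.length_scale <= 0:
            raise InvalidSpecError("length_scale must be > 0")


def simulate_coupled_cohort(spec: BehaviorCouplingSpec) -> tuple[Cohort, np.ndarray]:
    """Simulate a cohort whose synchrony structure tracks behavioral scores."""
    spec.validate()
    scores = np.asarray(spec.scores, dtype=float)
    kappa = spec.coupling_strength
    if spec.structure == "none" or kappa == 0:
        return simulate_shared_response(spec.base), scores

    n = spec.base.n_subjects
    if spec.structure == "annak":
        ranks = rankdata(scores)  # average-rank ties
        alpha0, _ = spec.base.weight_arrays()
        alpha = alpha0 + kappa * (ranks - 0.5) / n
        cohort = simulate_shared_response(spec.base, _alpha_override=alpha)
        return cohort, scores

    # nearest-neighbor: base cohort plus a kappa-weighted GP component whose
    # inter-subject correlation decays with the score gap
    cohort = simulate_shared_response(spec.base)
    K = np.exp(-np.abs(scores[:, None] - scores[None, :]) / spec.length_scale)
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
    # independent stream so the base draws are untouched
    rng = np.random.default_rng(np.random.SeedSequence([spec.base.seed, 0x6E6E]))
    for ch in range(spec.base.n_channels):
        basis = _smooth_signal(
            rng,
            spec.base.n_timepoints,
            spec.base.sampling_rate,
            spec.base.shared_signal_kind,
            size=(n,),
        )
        cohort.data[:, ch, :] += kappa * (L @ basis)
    return cohort, scores


# --------------------------------------------------------------------------
# raw optical intensities (Beer-Lambert forward model)
# --------------------------------------------------------------------------


@dataclass
class OpticalGeometry:
    """Source-detector geometry for the Beer-Lambert forward/inverse model.

    ``extinction`` has rows per wavelength and columns (HbO, HbR); it must be
    nonsingular, i.e. the two chromophores must have distinct absorption
    ratios at the two wavelengths.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    source_detector_distance_cm: float = 3.0
    dpf: tuple[float, float] = (6.0, 6.0)
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())

    def validate(self) -> None:
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2):
            raise InvalidSpecError("extinction must be 2x2 (wavelength x chromophore)")
        if abs(np.linalg.det(E)) < 1e-12 * np.abs(E).max() ** 2:
            from .types import InvalidGeometryError

            raise InvalidGeometryError("extinction matrix is singular")
        if self.source_detector_distance_cm <= 0 or min(self.dpf) <= 0:
            raise InvalidSpecError("distance and DPF must be positive")


def simulate_raw_intensity(
    hbo: np.ndarray,
    hbr: np.ndarray,
    geometry: OpticalGeometry | None = None,
    baseline_intensity: float | np.ndarray = 1.0,
    sampling_rate: float = 7.8,
    saturation_segments: list[tuple[int, float, float]] | None = None,
    white_noise_channels: list[int] | None = None,
    adc_ceiling: float | None = None,
    seed: int = 0,
) -> RawIntensity:
    """Forward-model raw light intensities from concentration time courses.

    ``OD(lam, t) = [eps_HbO(lam) dHbO(t) + eps_HbR(lam) dHbR(t)] * d * DPF(lam)``
    and ``I(lam, t) = I0(lam) * 10 ** (-OD)``.  Optional artifacts (saturation
    plateaus, white-noise channel replacement) are injected after the forward
    model.  ``saturation_segments`` entries are ``(channel, start_s, duration_s)``.
    """
    geometry = geometry or OpticalGeometry()
    geometry.validate()
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    if hbo.shape != hbr.shape:
        raise InvalidSpecError("hbo and hbr must have the same shape")
    n_ch, T = hbo.shape
    I0 = np.broadcast_to(np.asarray(baseline_intensity, dtype=float), (2, n_ch)).copy()
    if np.any(I0 <= 0):
        raise InvalidSpecError("baseline intensity must be positive")
    d = geometry.source_detector_distance_cm
    E = np.asarray(geometry.extinction, dtype=float)
    conc = np.stack([hbo, hbr])  # (2, n_ch, T)
    od = np.einsum("wc,cnt->wnt", E, conc)  # chromophore mix per wavelength
    od *= d * np.asarray(geometry.dpf)[:, None, None]
    intensity = I0[:, :, None] * 10.0 ** (-od)

    rng = np.random.default_rng(seed)
    ceiling = adc_ceiling
    if saturation_segments:
        if ceiling is None:
            ceiling = float(intensity.max()) * 1.5
        for ch, start_s, dur_s in saturation_segments:
            i0 = int(round(start_s * sampling_rate))
            i1 = i0 + int(round(dur_s * sampling_rate))
            intensity[:, ch, i0:i1] = ceiling
    if white_noise_channels:
        for ch in white_noise_channels:
            base = I0[:, ch, None]
            intensity[:, ch, :] = base * (
                1.0 + 0.01 * rng.standard_normal((2, T))
            )
    return RawIntensity(
        wavelengths=geometry.wavelengths,
        intensity=intensity,
        sampling_rate=sampling_rate,
        adc_ceiling=ceiling,
        baseline_intensity=I0,
    )


# --------------------------------------------------------------------------
# discrete-emotion ratings (two-part generative model)
# --------------------------------------------------------------------------


@dataclass
class RatingsGenSpec:
    """Two-part generative model for 0-100 discrete-emotion ratings.

    Each observation first draws a Bernoulli indicator of a *non-extreme*
    response from a logistic mixed model (log-odds scale, subject random
    intercept).  Extreme responses are coded at the boundary the emotion
    implies (raw 100 for negative emotions, raw 0 for joy).  Non-extreme
    responses are drawn from a Gaussian mixed model on the log-transformed
    scale and mapped back to raw units.

    Fixed-effect tuples are ordered (intercept, time, group, time x group),
    with time coded 0/1 (pre/post) and group 0/1 (control / mindfulness).
    Default magnitudes echo the fitted scale of the study's anger model:
    a residual SD near 0.6 and a subject intercept SD near 0.57 on the log
    scale, a logistic random-intercept SD near 2, and a strongly negative
    time x group log-odds effect (the trained group becomes more likely to
    respond at the extreme after training).
    """

    n_subjects: int = 72
    n_videos_per_session: int = 8
    n_sessions: int = 2
    logit_coefs: tuple[float, float, float, float] = (2.2, -0.54, -0.41, -2.2)
    gauss_coefs: tuple[float, float, float, float] = (2.78, 0.22, -0.05, 0.21)
    logit_random_sd: float = 2.0
    gauss_random_sd: float = 0.57
    residual_sd: float = 0.62
    emotion: str = "anger"
    seed: int = 0

    @property
    def emotion_polarity(self) -> str:
        if self.emotion in NEGATIVE_EMOTIONS:
            return "negative"
        if self.emotion in POSITIVE_EMOTIONS:
            return "positive"
        raise InvalidSpecError(
            f"emotion {self.emotion!r} has no extreme-response convention"
        )

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_videos_per_session < 1 or self.n_sessions < 1:
            raise InvalidSpecError("counts must be positive (n_subjects >= 2)")
        if min(self.logit_random_sd, self.gauss_random_sd, self.residual_sd) < 0:
            raise InvalidSpecError("standard deviations must be >= 0")
        self.emotion_polarity  # raises for unsupported emotions


_LOG_MAX = float(np.log(101.0))
_LOG_MIN = float(np.log(1.0 + 1e-9))


def simulate_ratings(spec: RatingsGenSpec) -> pd.DataFrame:
    """Simulate a long-format ratings table (subject, session, group, video,
    emotion, value) with raw values in [0, 100] and extremes exactly at the
    boundary."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    groups = np.zeros(n, dtype=int)
    groups[n // 2 :] = 1  # first half control (0), second half trained (1)
    u_logit = spec.logit_random_sd * rng.standard_normal(n)
    u_gauss = spec.gauss_random_sd * rng.standard_normal(n)

    rows = []
    b_l = spec.logit_coefs
    b_g = spec.gauss_coefs
    negative = spec.emotion_polarity == "negative"
    extreme_raw = 100.0 if negative else 0.0
    for i in range(n):
        g = groups[i]
        for t in range(spec.n_sessions):
            eta_l = b_l[0] + b_l[1] * t + b_l[2] * g + b_l[3] * t * g + u_logit[i]
            eta_g = b_g[0] + b_g[1] * t + b_g[2] * g + b_g[3] * t * g + u_gauss[i]
            p_nonextreme = expit(eta_l)
            nonext = rng.random(spec.n_videos_per_session) < p_nonextreme
            tvals = eta_g + spec.residual_sd * rng.standard_normal(
                spec.n_videos_per_session
            )
            tvals = np.clip(tvals, _LOG_MIN, _LOG_MAX)
            if negative:
                raw = 101.0 - np.exp(tvals)
            else:
                raw = np.exp(tvals) - 1.0
            raw = np.clip(raw, 0.0, 100.0)
            raw[~nonext] = extreme_raw
            for v in range(spec.n_videos_per_session):
                rows.append(
                    (
                        f"sub{i + 1:03d}",
                        t,
                        int(g),
                        f"vid{v + 1:02d}",
                        spec.emotion,
                        raw[v],
                    )
                )
    df = pd.DataFrame(
        rows, columns=["subject", "session", "group", "video", "emotion", "value"]
    )
    if df["value"].min() < 0 or df["value"].max() > 100:
        # clipping above guarantees this; guard against regressions
        raise AssertionError("generated ratings left the 0-100 scale")
    return df
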