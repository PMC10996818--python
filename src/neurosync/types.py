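"""Shared containers and error types for the neurosync pipeline.

The central objects are :class:`Cohort` (aligned multi-subject channel x time
hemodynamic matrices), :class:`RawIntensity` (dual-wavelength light intensity
prior to the Modified Beer-Lambert conversion), :class:`SimilarityMatrix`
(subject x subject (dis)similarity structures with a declared kind), and
:class:`PermutationResult` (an observed statistic with its permutation null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class NeurosyncError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(NeurosyncError, ValueError):
    """A simulation or analysis specification violates its invariants."""


class InvalidGeometryError(NeurosyncError, ValueError):
    """Optode geometry / extinction matrix is unusable (e.g. singular)."""


class DegenerateInputError(NeurosyncError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-tied scores)."""


class InvalidEventsError(NeurosyncError, ValueError):
    """Event table references samples outside the recording."""


class EmptyConditionError(NeurosyncError, ValueError):
    """No events match the requested condition."""


class InvalidBandError(NeurosyncError, ValueError):
    """Requested filter band is outside (0, Nyquist)."""


class NoUsableChannelsError(NeurosyncError, ValueError):
    """Channel quality control left no usable channels."""


@dataclass
class Cohort:
    """Aligned multi-subject hemodynamic time courses.

    Parameters
    ----------
    subjects
        Ordered subject identifiers, unique.
    data
        Array of shape ``(n_subjects, n_channels, n_time)``; typically
        standardized total hemoglobin.
    sampling_rate
        Sampling rate in Hz.
    group
        Optional per-subject group labels (same order as ``subjects``).
    channel_ids
        Optional channel names; defaults to ``ch01..chNN``.
    usable
        Optional boolean mask of shape ``(n_channels,)``; unusable channels
        are excluded from analyses.
    """

    subjects: list[str]
    data: np.ndarray
    sampling_rate: float
    group: list[str] | None = None
    channel_ids: list[str] | None = None
    usable: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidSpecError(
                f"cohort data must be (n_subjects, n_channels, n_time); got shape {self.data.shape}"
            )
        n_sub, n_ch, _ = self.data.shape
        if len(self.subjects) != n_sub:
            raise InvalidSpecError("subject id count does not match data")
        if len(set(self.subjects)) != n_sub:
            raise InvalidSpecError("duplicate subject ids")
        if self.group is not None and len(self.group) != n_sub:
            raise InvalidSpecError("group label count does not match data")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1:02d}" for i in range(n_ch)]
        elif len(self.channel_ids) != n_ch:
            raise InvalidSpecError("channel id count does not match data")
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def subset(self, indices: Sequence[int]) -> "Cohort":
        """Return a new cohort restricted to the given subject indices."""
        idx = list(indices)
        return Cohort(
            subjects=[self.subjects[i] for i in idx],
            data=self.data[idx],
            sampling_rate=self.sampling_rate,
            group=[self.group[i] for i in idx] if self.group is not None else None,
            channel_ids=list(self.channel_ids),
            usable=None if self.usable is None else self.usable.copy(),
            seed=self.seed,
        )


@dataclass
class RawIntensity:
    """Dual-wavelength raw light-intensity recording.

    ``intensity`` has shape ``(n_wavelengths, n_channels, n_time)`` with
    strictly positive values except where artifacts were injected.
    """

    wavelengths: tuple[float, float]
    intensity: np.ndarray
    sampling_rate: float
    channel_ids: list[str] | None = None
    adc_ceiling: float | None = None
    baseline_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[0] != 2:
            raise InvalidSpecError(
                "intensity must have shape (2 wavelengths, n_channels, n_time)"
            )
        if self.sampling_rate <= 0:
            raise InvalidSpecError("sampling_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i + 1:02d}" for i in range(self.intensity.shape[1])]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.intensity.shape[2]


SIMILARITY_KINDS = ("pearson_r", "sq_euclidean", "annak_similarity")


@dataclass
class SimilarityMatrix:
    """Symmetric subject-by-subject (dis)similarity structure.

    ``kind`` declares the metric: ``pearson_r`` (similarity, diagonal 1),
    ``sq_euclidean`` (dissimilarity, diagonal 0), or ``annak_similarity``
    (mean-rank similarity, diagonal rank_i / n).
    """

    values: np.ndarray
    kind: str
    subjects: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIMILARITY_KINDS:
            raise InvalidSpecError(f"unknown similarity kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidSpecError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidSpecError("similarity matrix must be symmetric")
        if self.kind == "pearson_r" and (np.nanmax(np.abs(v)) > 1 + 1e-9):
            raise InvalidSpecError("pearson_r entries must lie in [-1, 1]")
        if self.kind == "sq_euclidean" and np.nanmin(v) < -1e-12:
            raise InvalidSpecError("squared distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_distance(self) -> bool:
        return self.kind == "sq_euclidean"

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class PermutationResult:
    """Observed statistic with its permutation-null summary.

    ``p_value`` uses the add-one rule, so it is bounded below by
    ``1 / (n_perm + 1)`` and never equals zero.
    """

    statistic: float
    p_value: float
    n_perm: int
    seed: int
    scheme: str
    null_quantiles: dict[str, float] = field(default_factory=dict)
    alternative: str = "greater"
    extra: dict = field(default_factory=dict)


@dataclass
class ChannelQCReport:
    """Per-channel quality-control outcome.

    ``reason`` is ``ok``, ``saturation``, or ``white_noise``;
    ``usable`` is True iff ``reason == 'ok'``.
    """

    channel_ids: list[str]
    usable: np.ndarray
    reason: list[str]
    qcod: np.ndarray
    max_saturation_run_s: np.ndarray

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, dtype=bool)
        for ok, why in zip(self.usable, self.reason):
            if ok != (why == "ok"):
                raise InvalidSpecError("usable flag inconsistent with reason")

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass
class HemoTimecourse:
    """Hemoglobin concentration time courses after preprocessing.

    ``total`` is the per-channel z-scored (HbO - HbR) signal used by all
    synchrony analyses.  ``provenance`` records the applied steps in order.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    total: np.ndarray
    sampling_rate: float
    channel_ids: list[str] | None = None
    provenance: list[str] = field(default_factory=list)
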