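"""Intersubject correlation (ISC) and its permutation inference.

Pairwise ISC correlates every pair of subjects' channel time courses;
leave-one-out ISC correlates each subject with the mean time course of all
*other* subjects, which is the preferred individual-level statistic for
group comparisons.  Between-group synchrony is tested indirectly through
H0: ISC_within = ISC_between, with a null distribution built by subject-wise
permutation (random reassignment of subjects to groups, preserving group
sizes).  Within-group synchrony is tested against a circular-shift null that
preserves each subject's autocorrelation while destroying time-locking.

All correlations are Pearson.  The permutation machinery works on the
subject-by-subject Gram matrix of z-scored time courses, which makes the
per-permutation cost independent of the series length; a naive direct
computation is kept alongside and cross-checked in the tests.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import Cohort, InvalidSpecError, PermutationResult, SimilarityMatrix

__all__ = [
    "pairwise_isc",
    "loo_isc",
    "group_isc",
    "two_sample_statistic",
    "swp_two_sample_test",
    "one_sample_isc_test",
]


def _channel_matrix(cohort: Cohort, channel: int) -> np.ndarray:
    """Subjects x time matrix for one channel, with NaN/constant screening."""
    if cohort.usable is not None and not cohort.usable[channel]:
        raise InvalidSpecError(f"channel {channel} is flagged unusable")
    X = cohort.data[:, channel, :]
    return np.asarray(X, dtype=float)


def _zscore_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score rows (population sd); returns (Z, valid mask of non-constant rows)."""
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    valid = (sd > 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, valid


def _drop_constant(X: np.ndarray, subjects: list[str]) -> tuple[np.ndarray, list[str]]:
    Z, valid = _zscore_rows(X)
    if not valid.all():
        dropped = [s for s, v in zip(subjects, valid) if not v]
        warnings.warn(f"constant time course(s) excluded: {dropped}")
    return Z[valid], [s for s, v in zip(subjects, valid) if v]


def pairwise_isc(cohort: Cohort, channel: int = 0) -> SimilarityMatrix:
    """Subject-by-subject Pearson correlation matrix for one channel."""
    X = _channel_matrix(cohort, channel)
    if X.shape[0] < 2:
        raise InvalidSpecError("pairwise ISC needs >= 2 subjects")
    Z, kept = _drop_constant(X, cohort.subjects)
    if Z.shape[0] < 2:
        raise InvalidSpecError("fewer than 2 non-constant subjects")
    T = Z.shape[1]
    R = (Z @ Z.T) / T
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2
    return SimilarityMatrix(values=R, kind="pearson_r", subjects=kept)


def loo_isc(cohort: Cohort, channel: int = 0) -> np.ndarray:
    """Leave-one-out ISC: r(subject, mean of all other subjects) per subject.

    Each subject's time course is z-scored before averaging, so the statistic
    is invariant to per-subject gain and offset.  Constant subjects get NaN.
    """
    X = _channel_matrix(cohort, channel)
    n = X.shape[0]
    if n < 2:
        raise InvalidSpecError("leave-one-out ISC needs >= 2 subjects")
    Z, valid = _zscore_rows(X)
    out = np.full(n, np.nan)
    if valid.sum() >= 2:
        out[valid] = _loo_from_rows(Z[valid])
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def group_isc(cohort: Cohort, channel: int = 0, method: str = "mean") -> float:
    """Group-level ISC: mean (default) or Fisher-z mean of leave-one-out values."""
    vals = loo_isc(cohort, channel)
    vals = vals[np.isfinite(vals)]
    if method == "mean":
        return float(vals.mean())
    if method == "fisher_z":
        z = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
        return float(np.tanh(z.mean()))
    raise InvalidSpecError(f"unknown summary method {method!r}")


# --------------------------------------------------------------------------
# two-sample (within- vs between-group) statistic
# --------------------------------------------------------------------------


def two_sample_statistic(
    cohortA: Cohort, cohortB: Cohort, channel: int = 0
) -> tuple[float, float, float]:
    """(within_mean, between_mean, difference) for one channel.

    Within-group values are each subject's leave-one-out ISC against its own
    group; between-group values correlate each subject with the *full* mean
    time course of the other group (there is no own-subject to leave out
    there).  The difference within - between is the test statistic.
    """
    XA = _channel_matrix(cohortA, channel)
    XB = _channel_matrix(cohortB, channel)
    if XA.shape[1] != XB.shape[1]:
        raise InvalidSpecError("groups must share the time axis")
    ZA, vA = _zscore_rows(XA)
    ZB, vB = _zscore_rows(XB)
    if not (vA.all() and vB.all()):
        warnings.warn("constant subject(s) excluded from the two-sample statistic")
    ZA, ZB = ZA[vA], ZB[vB]
    if ZA.shape[0] < 3 or ZB.shape[0] < 3:
        raise InvalidSpecError("each group needs >= 3 non-constant subjects")
    T = ZA.shape[1]
    within = np.concatenate([_loo_from_rows(ZA), _loo_from_rows(ZB)])
    sA, sB = ZA.sum(axis=0), ZB.sum(axis=0)
    between = np.concatenate(
        [
            (ZA @ sB) / np.sqrt(T * (sB @ sB)),
            (ZB @ sA) / np.sqrt(T * (sA @ sA)),
        ]
    )
    w, b = float(within.mean()), float(between.mean())
    return w, b, w - b


def _gram_two_sample(
    G: np.ndarray, T: int, members: np.ndarray
) -> np.ndarray:
    """Vectorized within-between difference from the Gram matrix of z-scored rows.

    ``G = Z @ Z.T`` with rows of Z exactly zero-mean, unit-population-sd
    (so ``G[i, i] == T``).  ``members`` is (n_perm, n) boolean, True = group A.
    Returns the difference statistic per permutation.
    """
    n = G.shape[0]
    diag = np.full(n, float(T))
    stats = np.empty(members.shape[0])
    for k, mA in enumerate(members):
        mB = ~mA
        gA = G @ mA  # g_i = sum_{j in A} G[ij]
        gB = G @ mB
        QA = float(mA @ gA)
        QB = float(mB @ gB)
        # within: r(x_i, sum_{j in own group, j != i} x_j)
        own_g = np.where(mA, gA, gB)
        own_Q = np.where(mA, QA, QB)
        num_w = own_g - diag
        den_w = np.sqrt(T * (own_Q - 2 * own_g + diag))
        within = num_w / den_w
        # between: r(x_i, sum over other group)
        other_g = np.where(mA, gB, gA)
        other_Q = np.where(mA, QB, QA)
        between = other_g / np.sqrt(T * other_Q)
        stats[k] = within.mean() - between.mean()
    return stats


def _null_summary(null: np.ndarray) -> dict[str, float]:
    qs = np.percentile(null, [2.5, 50, 97.5])
    return {"q025": float(qs[0]), "q50": float(qs[1]), "q975": float(qs[2])}


def swp_two_sample_test(
    cohortA: Cohort,
    cohortB: Cohort,
    channels: list[int] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "greater",
) -> list[PermutationResult]:
    """Subject-wise permutation test of H0: ISC_within = ISC_between.

    Subjects are randomly reassigned to groups (preserving group sizes) and
    the within-minus-between statistic recomputed for each permutation.
    One-sided (within > between) by default; ``alternative='two-sided'``
    compares absolute values.  Returns one result per requested channel.
    """
    if set(cohortA.subjects) & set(cohortB.subjects):
        raise InvalidSpecError("duplicate subject ids across groups")
    nA, nB = cohortA.n_subjects, cohortB.n_subjects
    if nA + nB < 6:
        raise InvalidSpecError("combined sample must be >= 6 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    if channels is None:
        channels = list(range(cohortA.n_channels))
    rng = np.random.default_rng(seed)
    n = nA + nB
    members = np.zeros((n_perm, n), dtype=bool)
    for k in range(n_perm):
        idx = rng.permutation(n)[:nA]
        members[k, idx] = True

    results = []
    for ch in channels:
        X = np.vstack([_channel_matrix(cohortA, ch), _channel_matrix(cohortB, ch)])
        Z, valid = _zscore_rows(X)
        if not valid.all():
            raise InvalidSpecError("constant time course in two-sample test input")
        T = Z.shape[1]
        G = Z @ Z.T
        observed_members = np.zeros((1, n), dtype=bool)
        observed_members[0, :nA] = True
        obs = float(_gram_two_sample(G, T, observed_members)[0])
        null = _gram_two_sample(G, T, members)
        if alternative == "greater":
            exceed = int(np.sum(null >= obs))
        elif alternative == "two-sided":
            exceed = int(np.sum(np.abs(null) >= abs(obs)))
        else:
            raise InvalidSpecError(f"unknown alternative {alternative!r}")
        p = (1 + exceed) / (n_perm + 1)
        results.append(
            PermutationResult(
                statistic=obs,
                p_value=p,
                n_perm=n_perm,
                seed=seed,
                scheme="group_relabel",
                null_quantiles=_null_summary(null),
                alternative=alternative,
                extra={"channel": ch},
            )
        )
    return results


# --------------------------------------------------------------------------
# one-sample (within-group synchrony) test
# --------------------------------------------------------------------------


def one_sample_isc_test(
    cohort: Cohort,
    channel: int = 0,
    n_perm: int = 5000,
    seed: int = 0,
    scheme: str = "circular_shift",
) -> PermutationResult:
    """Test whether a group shows above-chance synchrony on one channel.

    The statistic is the mean leave-one-out ISC.  The null independently
    circular-shifts each subject's time course by a random nonzero offset,
    destroying stimulus time-locking while preserving each subject's
    autocorrelation, and recomputes the statistic.
    """
    if scheme != "circular_shift":
        raise InvalidSpecError(f"unknown scheme {scheme!r}")
    X = _channel_matrix(cohort, channel)
    n, T = X.shape
    if n < 3:
        raise InvalidSpecError("one-sample test needs >= 3 subjects")
    if T < 100:
        raise InvalidSpecError("circular-shift null needs T >= 100")
    Z, valid = _zscore_rows(X)
    if not valid.all():
        raise InvalidSpecError("constant time course in one-sample test input")
    obs = float(np.mean(_loo_from_rows(Z)))

    rng = np.random.default_rng(seed)
    # offsets in 1..T-1 (the identity shift is excluded from the null)
    offsets = rng.integers(1, T, size=(n_perm, n))
    col = np.arange(T)
    null = np.empty(n_perm)
    for k in range(n_perm):
        idx = (col[None, :] + offsets[k][:, None]) % T
        shifted = np.take_along_axis(Z, idx, axis=1)
        null[k] = float(np.mean(_loo_from_rows(shifted)))
    exceed = int(np.sum(null >= obs))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        statistic=obs,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        scheme="circular_shift",
        null_quantiles=_null_summary(null),
        alternative="greater",
        extra={"channel": channel},
    )


def _loo_from_rows(Z: np.ndarray) -> np.ndarray:
    """Leave-one-out ISC values for rows that are already zero-mean unit-sd."""
    n, T = Z.shape
    total = Z.sum(axis=0)
    refs = (total[None, :] - Z) / (n - 1)
    refs = refs - refs.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Z, refs)
    den = np.sqrt(T * np.einsum("ij,ij->i", refs, refs))
    return np.clip(num / den, -1.0, 1.0)
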