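"""Intersubject representational similarity analysis (IS-RSA).

Two similarity models are implemented for relating a subject-by-subject
neural similarity structure to a behavioral one:

* **Nearest Neighbor (NN)** — pairwise squared Euclidean distance between
  scores (or time courses): subjects adjacent in behavioral rank are most
  similar.  On per-subject z-scored time courses of length T this distance
  relates to Pearson correlation r through ``D = 2 T (1 - r)``.
* **Anna Karenina (AnnaK)** — mean of the two subjects' behavioral ranks
  divided by the number of subjects: high scorers are predicted to be
  mutually similar while low scorers are idiosyncratic.

Model fit is the correlation (Spearman by default) between the strictly
upper triangles of the neural and behavioral matrices; inference uses
subject-wise permutation (joint row/column relabeling of the behavioral
matrix).  A Mantel test and an NN-vs-AnnaK paired comparison across channels
complete the model-selection pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .isc import pairwise_isc
from .types import (
    Cohort,
    DegenerateInputError,
    InvalidSpecError,
    PermutationResult,
    SimilarityMatrix,
)

__all__ = [
    "nn_distance_matrix",
    "annak_similarity_matrix",
    "isrsa_correlation",
    "swp_isrsa_test",
    "mantel_test",
    "compare_similarity_models",
    "isrsa_per_channel",
    "ModelComparison",
]


def nn_distance_matrix(x: np.ndarray) -> SimilarityMatrix:
    """Squared Euclidean distance between subjects' scores or time courses.

    ``x`` is either a length-n vector of scalar scores ((s_i - s_j)^2) or an
    (n, T) matrix of time courses (sum over t of squared differences).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        D = (x[:, None] - x[None, :]) ** 2
    elif x.ndim == 2:
        sq = np.einsum("ij,ij->i", x, x)
        D = sq[:, None] + sq[None, :] - 2 * (x @ x.T)
        D = np.maximum(D, 0.0)
    else:
        raise InvalidSpecError("x must be per-subject scalars or time courses")
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return SimilarityMatrix(values=D, kind="sq_euclidean")


def annak_similarity_matrix(scores: np.ndarray) -> SimilarityMatrix:
    """Anna-Karenina similarity: (rank_i + rank_j) / (2 n), average-rank ties."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise InvalidSpecError("scores must be a vector of >= 2 subjects")
    if np.ptp(scores) == 0:
        raise DegenerateInputError(
            "all scores tied: AnnaK similarity matrix would be constant"
        )
    ranks = stats.rankdata(scores)
    n = scores.size
    S = (ranks[:, None] + ranks[None, :]) / (2 * n)
    return SimilarityMatrix(values=S, kind="annak_similarity")


def _as_similarity_upper(m: SimilarityMatrix) -> np.ndarray:
    """Strict upper triangle, oriented so higher = more similar."""
    u = m.upper_triangle()
    return -u if m.is_distance else u


def isrsa_correlation(
    neural: SimilarityMatrix,
    behavior: SimilarityMatrix,
    method: str = "spearman",
) -> float:
    """Correlation of the two matrices' strictly-upper triangles.

    Distances are negated internally so both operands read "higher = more
    similar"; the orientation is determined by each matrix's declared kind.
    """
    if neural.n != behavior.n:
        raise InvalidSpecError("matrices must share the subject set and order")
    if neural.n < 3:
        raise InvalidSpecError("IS-RSA needs >= 3 subjects")
    a = _as_similarity_upper(neural)
    b = _as_similarity_upper(behavior)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant similarity matrix: correlation undefined")
    if method == "spearman":
        r = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        r = stats.pearsonr(a, b).statistic
    else:
        raise InvalidSpecError(f"unknown method {method!r}")
    return float(r)


def _sym_from_upper(values: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = values
    return M + M.T


def _joint_permutation_null(
    a_upper: np.ndarray,
    b_matrix: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null correlations from joint row/column relabelings of ``b_matrix``.

    Both vectors' means/sds are invariant under relabeling (the upper-triangle
    multiset is preserved), so only the cross-product varies per permutation.
    """
    n = b_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    a_c = a_upper - a_upper.mean()
    b_upper = b_matrix[iu]
    b_sd_term = np.sqrt(np.sum((b_upper - b_upper.mean()) ** 2))
    a_sd_term = np.sqrt(np.sum(a_c**2))
    b_mean = b_upper.mean()
    null = np.empty(n_perm)
    for k in range(n_perm):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break  # the identity relabeling is excluded from the null
        bp = b_matrix[np.ix_(perm, perm)][iu]
        null[k] = np.dot(a_c, bp - b_mean) / (a_sd_term * b_sd_term)
    return null


def swp_isrsa_test(
    neural: SimilarityMatrix,
    behavior: SimilarityMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    method: str = "spearman",
    alternative: str = "two-sided",
) -> PermutationResult:
    """Subject-wise permutation test of the IS-RSA correlation.

    The behavioral matrix's rows and columns are jointly permuted by a random
    subject relabeling; p uses the add-one rule.  Two-sided by default
    (``|null r| >= |observed r|``); ``alternative='greater'`` is one-sided.
    """
    obs = isrsa_correlation(neural, behavior, method=method)
    n = neural.n
    a = _as_similarity_upper(neural)
    b_mat = _sym_from_upper(_as_similarity_upper(behavior), n)
    if method == "spearman":
        a = stats.rankdata(a)
        b_mat = _sym_from_upper(stats.rankdata(b_mat[np.triu_indices(n, k=1)]), n)
    rng = np.random.default_rng(seed)
    null = _joint_permutation_null(a, b_mat, n_perm, rng)
    if alternative == "two-sided":
        exceed = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    elif alternative == "greater":
        exceed = int(np.sum(null >= obs - 1e-12))
    else:
        raise InvalidSpecError(f"unknown alternative {alternative!r}")
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        statistic=obs,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        scheme="group_relabel",
        null_quantiles={
            "q025": float(np.percentile(null, 2.5)),
            "q50": float(np.percentile(null, 50)),
            "q975": float(np.percentile(null, 97.5)),
        },
        alternative=alternative,
        extra={"method": method},
    )


def mantel_test(
    m1: SimilarityMatrix,
    m2: SimilarityMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: linear correlation of upper triangles under a joint
    row/column permutation null.  Returns (r, p)."""
    if m1.n != m2.n:
        raise InvalidSpecError("matrices must have the same shape")
    if m1.n < 3:
        raise InvalidSpecError("Mantel test needs >= 3 subjects")
    a = _as_similarity_upper(m1)
    b = _as_similarity_upper(m2)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant matrix: Mantel correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    b_mat = _sym_from_upper(b, m1.n)
    rng = np.random.default_rng(seed)
    null = _joint_permutation_null(a, b_mat, n_perm, rng)
    if alternative == "greater":
        exceed = int(np.sum(null >= r - 1e-12))
    elif alternative == "two-sided":
        exceed = int(np.sum(np.abs(null) >= abs(r) - 1e-12))
    else:
        raise InvalidSpecError(f"unknown alternative {alternative!r}")
    p = (1 + exceed) / (n_perm + 1)
    return r, p


@dataclass
class ModelComparison:
    """Paired comparison of AnnaK vs NN IS-RSA fits across channels."""

    t_statistic: float
    p_value: float
    table: pd.DataFrame
    note: str = ""


def compare_similarity_models(
    fits_annak: np.ndarray, fits_nn: np.ndarray
) -> ModelComparison:
    """Paired t-test across channels on (r_annak - r_nn).

    A zero-variance, nonzero difference vector (a perfectly consistent
    advantage of one model) has no finite t; it is flagged rather than
    reported as a number.
    """
    a = np.asarray(fits_annak, dtype=float)
    b = np.asarray(fits_nn, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidSpecError("fit vectors must be 1-D with equal channel sets")
    if a.size < 2:
        raise InvalidSpecError("model comparison needs >= 2 channels")
    diffs = a - b
    table = pd.DataFrame(
        {
            "channel": np.arange(a.size),
            "r_annak": a,
            "r_nn": b,
            "difference": diffs,
        }
    )
    scale = max(1.0, float(np.abs(diffs).max()))
    if float(np.std(diffs, ddof=1)) <= 1e-12 * scale:
        if abs(float(diffs.mean())) <= 1e-12 * scale:
            return ModelComparison(0.0, 1.0, table, note="identical fits")
        return ModelComparison(
            float(np.sign(diffs.mean()) * np.inf),
            0.0,
            table,
            note="perfectly consistent difference (zero variance)",
        )
    t, p = stats.ttest_rel(a, b)
    return ModelComparison(float(t), float(p), table)


def isrsa_per_channel(
    cohort: Cohort,
    scores: np.ndarray,
    model: str = "annak",
    neural_metric: str = "correlation",
    method: str = "spearman",
    n_perm: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """IS-RSA fit (and optionally permutation p) for every channel.

    ``model`` selects the behavioral matrix (AnnaK mean-rank similarity or NN
    squared Euclidean distance on scores); ``neural_metric`` selects the
    neural matrix (pairwise Pearson correlation or squared Euclidean
    time-course distance — equivalent up to orientation on z-scored data).
    """
    scores = np.asarray(scores, dtype=float)
    if model == "annak":
        behavior = annak_similarity_matrix(scores)
    elif model == "nn":
        behavior = nn_distance_matrix(scores)
    else:
        raise InvalidSpecError(f"unknown model {model!r}")
    rows = []
    for ch in range(cohort.n_channels):
        if cohort.usable is not None and not cohort.usable[ch]:
            continue
        if neural_metric == "correlation":
            neural = pairwise_isc(cohort, ch)
        elif neural_metric == "euclidean":
            neural = nn_distance_matrix(cohort.data[:, ch, :])
        else:
            raise InvalidSpecError(f"unknown neural metric {neural_metric!r}")
        if n_perm:
            res = swp_isrsa_test(
                neural, behavior, n_perm=n_perm, seed=seed + ch, method=method
            )
            rows.append((ch, model, res.statistic, res.p_value, n_perm, seed + ch))
        else:
            r = isrsa_correlation(neural, behavior, method=method)
            rows.append((ch, model, r, np.nan, 0, seed))
    return pd.DataFrame(
        rows, columns=["channel", "model", "r", "p", "n_perm", "seed"]
    )
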