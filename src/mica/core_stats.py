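"""Concordance statistics for multi-class expression patterns across studies.

This module implements the building blocks of mutual-information concordance
analysis (MICA) for one gene measured in ``S`` studies, each with samples
assigned to the same ``K`` classes:

* the multi-class correlation (MCC) between two studies, derived from an
  equal-weight Gaussian mixture model over classes;
* min-MCC, the minimum pairwise MCC over all study pairs (the all-study
  concordance statistic of prior art);
* MI+, the one-sided corrected mutual information ``-1/2 log(1 - (rho+)^2)``
  of a bivariate normal, with negative correlations zeroed so only positive
  concordance counts;
* gMI (total correlation) and gMI+, the multi-study generalizations built
  from the determinant of the pairwise (one-sided) MCC matrix.

All functions accept either a single gene (1-D expression vectors) or a
stack of ``G`` genes sharing the sample layout (2-D arrays of shape
``(G, n)``), in which case they broadcast over genes.

Notes
-----
gMI is defined through covariance matrices as
``-1/2 (log|Sigma| - sum_s log sigma_s^2)``; because ``Sigma`` has
``sigma_s^2`` on its diagonal this equals ``-1/2 log|R|`` where ``R`` is the
correlation (pairwise-MCC) matrix. The implementation works in correlation
form throughout, which is numerically safer and manifestly scale-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StudyData",
    "ClassMoments",
    "StudyMixtureMoments",
    "ConcordanceMatrix",
    "class_moments",
    "mixture_moments",
    "mcc",
    "concordance_matrix",
    "min_mcc",
    "mi_plus",
    "gmi",
    "gmi_plus",
    "pd_repair_count",
]

logger = logging.getLogger(__name__)

#: correlations outside [-1 - RHO_TOL, 1 + RHO_TOL] are rejected; inside, clipped.
RHO_TOL = 1e-8
#: squared correlations are clamped below 1 - MI_CLAMP before the log so that
#: boundary correlations (rho = +/-1) yield large finite statistics that still
#: rank above every interior value.
MI_CLAMP = 1e-12
#: relative eigenvalue floor used when a one-sided MCC matrix loses positive
#: definiteness (zeroing negative entries can do that); see gmi_plus.
EIG_FLOOR = 1e-8

_pd_repairs = 0


def pd_repair_count() -> int:
    """Number of times a one-sided MCC matrix needed eigenvalue repair."""
    return _pd_repairs


@dataclass(eq=False)
class StudyData:
    """Expression values and class labels for one study.

    Parameters
    ----------
    values : array_like
        Expression values, shape ``(n,)`` for one gene or ``(G, n)`` for a
        stack of genes sharing the same samples. Arbitrary (already
        normalized) expression units.
    labels : array_like
        Class label per sample, shape ``(n,)``. Labels may be any hashable
        scalar; studies to be compared must share the same label set.
    study : str
        Study identifier.
    """

    values: np.ndarray
    labels: np.ndarray
    study: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D (one gene) or 2-D (genes x samples)")
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.values.shape[-1] != self.labels.shape[0]:
            raise ValueError(
                f"study {self.study!r}: {self.values.shape[-1]} expression columns "
                f"but {self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(np.atleast_2d(self.values)))
            g, i = bad[0]
            raise ValueError(
                f"study {self.study!r}: non-finite expression value at "
                f"gene index {g}, sample index {i}"
            )

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class labels present in this study."""
        return np.unique(self.labels)

    @property
    def n_samples(self) -> int:
        return int(self.labels.shape[0])

    @property
    def n_genes(self) -> int:
        return 1 if self.values.ndim == 1 else int(self.values.shape[0])

    def class_counts(self, classes: np.ndarray | None = None) -> np.ndarray:
        classes = self.classes if classes is None else np.asarray(classes)
        return np.array([(self.labels == c).sum() for c in classes])

    def onehot(self, classes: np.ndarray | None = None) -> np.ndarray:
        """Indicator matrix ``(n, K)``; raises if a requested class is absent."""
        classes = self.classes if classes is None else np.asarray(classes)
        ind = (self.labels[:, None] == classes[None, :]).astype(float)
        missing = classes[ind.sum(axis=0) == 0]
        if missing.size:
            raise ValueError(
                f"study {self.study!r}: no samples for class {missing[0]!r}"
            )
        return ind


@dataclass(eq=False)
class ClassMoments:
    """Per-class mean and maximum-likelihood variance estimates.

    ``mean`` and ``var`` have shape ``(..., K)``; ``n`` has shape ``(K,)``.
    The variance uses the maximum-likelihood divisor ``n_k`` (no Bessel
    correction), so single-sample classes have variance exactly 0.
    """

    mean: np.ndarray
    var: np.ndarray
    n: np.ndarray
    classes: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.classes.shape[0])


@dataclass(eq=False)
class StudyMixtureMoments:
    """Mean and variance of the class-mixture distribution of one study."""

    mean: np.ndarray
    var: np.ndarray
    weights: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.var)


@dataclass(eq=False)
class ConcordanceMatrix:
    """Pairwise MCC values between studies.

    ``rho`` is symmetric with unit diagonal (the diagonal is definitional,
    not estimated), shape ``(S, S)`` or ``(G, S, S)``. ``sigma`` holds the
    per-study mixture standard deviations, shape ``(S,)`` or ``(G, S)``.
    """

    rho: np.ndarray
    sigma: np.ndarray
    studies: list = field(default_factory=list)

    @property
    def n_studies(self) -> int:
        return int(self.rho.shape[-1])


def _check_weights(weights, K: int) -> np.ndarray:
    if weights is None:
        return np.full(K, 1.0 / K)
    w = np.asarray(weights, dtype=float)
    if w.shape != (K,):
        raise ValueError(f"expected {K} class weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("class weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("class weights must sum to 1")
    return w


def class_moments(study: StudyData, classes: Sequence | None = None) -> ClassMoments:
    """Estimate per-class means and ML variances for one study.

    The estimators are the sample mean and the mean of squared deviations
    with divisor ``n_k`` per class.
    """
    cls = study.classes if classes is None else np.asarray(classes)
    ind = study.onehot(cls)
    n_k = ind.sum(axis=0)
    mean = (study.values @ ind) / n_k
    ex2 = (study.values**2 @ ind) / n_k
    var = np.maximum(ex2 - mean**2, 0.0)
    return ClassMoments(mean=mean, var=var, n=n_k.astype(int), classes=cls)


def mixture_moments(
    moments: ClassMoments, weights: Sequence[float] | None = None
) -> StudyMixtureMoments:
    """Moments of the mixture-over-classes distribution of a study.

    With weights ``w_k`` (uniform ``1/K`` by default):
    ``mu = sum_k w_k mu_k`` and ``var = sum_k w_k (var_k + mu_k^2) - mu^2``.
    """
    w = _check_weights(weights, moments.n_classes)
    mu = moments.mean @ w
    var = (moments.var + moments.mean**2) @ w - mu**2
    return StudyMixtureMoments(mean=mu, var=np.maximum(var, 0.0), weights=w)


def _mcc_from_moments(
    mx: ClassMoments, my: ClassMoments, w: np.ndarray
) -> np.ndarray:
    """MCC from per-class moments of two studies sharing a weight vector."""
    mix_x = mixture_moments(mx, w)
    mix_y = mixture_moments(my, w)
    num = (mx.mean * my.mean) @ w - mix_x.mean * mix_y.mean
    den = mix_x.sd * mix_y.sd
    den = np.asarray(den, dtype=float)
    degenerate = den == 0
    if np.any(degenerate):
        warnings.warn(
            "constant study (zero mixture variance): MCC set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return _clip_rho(rho)


def _clip_rho(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1.0 + RHO_TOL):
        raise ValueError("correlation outside [-1, 1] beyond numerical tolerance")
    return np.clip(rho, -1.0, 1.0)


def _common_classes(studies: Sequence[StudyData]) -> np.ndarray:
    cls = studies[0].classes
    for s in studies[1:]:
        if not np.array_equal(s.classes, cls):
            raise ValueError(
                f"studies {studies[0].study!r} and {s.study!r} have different "
                f"class sets: {cls.tolist()} vs {s.classes.tolist()}"
            )
    return cls


def mcc(
    x: StudyData, y: StudyData, weights: Sequence[float] | None = None
) -> float | np.ndarray:
    """Multi-class correlation between two studies.

    ``MCC(X, Y) = (sum_k w_k mu_Xk mu_Yk - mu_X mu_Y) / (sigma_X sigma_Y)``
    where the mixture moments use the same weight vector (uniform by
    default). The value lies in ``[-1, 1]``: the numerator is a weighted
    covariance of class means while the denominators also carry the
    within-class variance.

    A study with zero mixture variance yields MCC 0 with a warning: the
    ratio is undefined and 0 encodes "no evidence of concordance".
    """
    cls = _common_classes([x, y])
    w = _check_weights(weights, len(cls))
    return _mcc_from_moments(class_moments(x, cls), class_moments(y, cls), w)


def concordance_matrix(
    studies: Sequence[StudyData],
    weights: Sequence[float] | None | str = None,
) -> ConcordanceMatrix:
    """All pairwise MCC values among ``S >= 2`` studies.

    ``weights`` may be a probability vector shared by all pairs, ``None``
    (uniform), or the string ``"observed"`` in which case each pair uses the
    pooled class proportions of that pair of studies (a common weight vector
    per pair keeps ``|MCC| <= 1``).
    """
    S = len(studies)
    if S < 2:
        raise ValueError("need at least two studies")
    cls = _common_classes(studies)
    K = len(cls)
    mom = [class_moments(s, cls) for s in studies]

    observed = isinstance(weights, str)
    if observed:
        if weights != "observed":
            raise ValueError(f"unknown weight mode {weights!r}")
        w_common = None
    else:
        w_common = _check_weights(weights, K)

    n_genes = np.broadcast(*[m.mean for m in mom]).shape[:-1]
    rho = np.ones(n_genes + (S, S))
    sigma = np.empty(n_genes + (S,))
    for i in range(S):
        w_i = mom[i].n / mom[i].n.sum() if observed else w_common
        sigma[..., i] = mixture_moments(mom[i], w_i).sd
    for i in range(S):
        for j in range(i + 1, S):
            if observed:
                n_pair = mom[i].n + mom[j].n
                w = n_pair / n_pair.sum()
            else:
                w = w_common
            r = _mcc_from_moments(mom[i], mom[j], w)
            rho[..., i, j] = r
            rho[..., j, i] = r
    return ConcordanceMatrix(rho=rho, sigma=sigma, studies=[s.study for s in studies])


def min_mcc(cm: ConcordanceMatrix) -> float | np.ndarray:
    """Minimum pairwise MCC over all study pairs (diagonal excluded)."""
    S = cm.n_studies
    if S < 2:
        raise ValueError("need at least two studies")
    iu, ju = np.triu_indices(S, k=1)
    out = cm.rho[..., iu, ju].min(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def mi_plus(rho) -> float | np.ndarray:
    """One-sided corrected mutual information of a bivariate normal.

    ``MI+ = -1/2 log(1 - (rho+)^2)`` with ``rho+ = rho * 1[rho > 0]``; zero
    for non-positive correlations, strictly increasing on ``(0, 1)``. At the
    boundary ``rho = 1`` the squared correlation is clamped just below 1 so
    the statistic is large but finite and still ranks above all interior
    values. Natural-log units (nats).
    """
    rp = np.maximum(_clip_rho(rho), 0.0)
    out = -0.5 * np.log1p(-np.minimum(rp**2, 1.0 - MI_CLAMP))
    return float(out) if np.ndim(out) == 0 else out


def _logdet_clipped(mat: np.ndarray) -> np.ndarray:
    """log-determinant of symmetric matrices with eigenvalue repair.

    Eigenvalues below ``EIG_FLOOR`` times the largest one are raised to that
    floor (the smallest intervention that keeps the log-determinant defined
    and preserves the ordering of statistics); repairs are counted.
    """
    global _pd_repairs
    eig = np.linalg.eigvalsh(mat)
    floor = EIG_FLOOR * np.maximum(eig[..., -1:], EIG_FLOOR)
    n_bad = int(np.count_nonzero(eig < floor))
    if n_bad:
        _pd_repairs += n_bad
        logger.debug("eigenvalue repair applied to %d eigenvalue(s)", n_bad)
    return np.sum(np.log(np.maximum(eig, floor)), axis=-1)


def _one_sided(rho: np.ndarray) -> np.ndarray:
    """Zero negative off-diagonal correlations; force a unit diagonal."""
    S = rho.shape[-1]
    rp = np.maximum(rho, 0.0)
    idx = np.arange(S)
    rp[..., idx, idx] = 1.0
    return rp


def gmi_plus(cm: ConcordanceMatrix) -> float | np.ndarray:
    """Generalized one-sided corrected mutual information (gMI+), in nats.

    ``gMI+ = -1/2 (log|Sigma+| - sum_s log sigma_s^2) = -1/2 log|R+|``,
    where ``R+`` is the pairwise MCC matrix with negative entries zeroed.
    Zero when no pair is positively concordant; a study with zero mixture
    variance has zero correlations (see :func:`mcc`) and drops out of the
    determinant, i.e. contributes as independent.

    ``R+`` can lose positive definiteness after the one-sided truncation;
    eigenvalues are then floored (see ``EIG_FLOOR``) before the log.
    """
    if cm.n_studies < 2:
        raise ValueError("need at least two studies")
    val = np.maximum(-0.5 * _logdet_clipped(_one_sided(np.array(cm.rho))), 0.0)
    return float(val) if np.ndim(val) == 0 else val


def gmi(cm: ConcordanceMatrix) -> float | np.ndarray:
    """Total correlation (two-sided gMI) of the studies, in nats.

    ``gMI = -1/2 (log|Sigma| - sum_s log sigma_s^2) = -1/2 log|R|``. Requires
    a positive-definite correlation matrix (and hence no degenerate study).
    """
    if cm.n_studies < 2:
        raise ValueError("need at least two studies")
    if np.any(cm.sigma == 0):
        raise ValueError("gMI undefined for a study with zero mixture variance")
    sign, logdet = np.linalg.slogdet(cm.rho)
    if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
        raise ValueError("MCC matrix is not positive definite")
    val = np.maximum(-0.5 * logdet, 0.0)
    return float(val) if np.ndim(val) == 0 else val
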