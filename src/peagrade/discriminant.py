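"""Linear discriminant analysis with nearest-Mahalanobis classification.

Implements the statistical core of the grading pipeline: per-feature
one-way F screening with an SVD linear-independence check, LDA fitting
(per-class means + pooled within-class covariance), classification by
minimum Mahalanobis distance to a class mean (equal priors; ties broken
by declared class order), greedy forward feature selection, and
Mahalanobis-distance diagnostics split by defect status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg, stats

from .features import FEATURE_NAMES, SampleRecord

__all__ = [
    "LDAModel",
    "Prediction",
    "ScreenReport",
    "MahalanobisSummary",
    "SingularCovarianceError",
    "record_label",
    "anova_f",
    "screen_features",
    "fit_lda",
    "classify",
    "classify_records",
    "forward_select",
    "accuracy",
    "mahalanobis_summary",
]

RANK_TOLERANCE = 1e-8

DEFECT_LABELS = ("defective", "non-defective")


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular; reduce the feature set."""


def record_label(record: SampleRecord, target: str = "grade") -> str:
    """The class label of a record for a given target field."""
    if target == "grade":
        return record.grade
    if target == "defect":
        return DEFECT_LABELS[0] if record.defective else DEFECT_LABELS[1]
    raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class LDAModel:
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    class_means: np.ndarray  # (K, p)
    pooled_cov: np.ndarray  # (p, p)
    pooled_cov_inv: np.ndarray  # (p, p)
    _cho: tuple = field(repr=False, default=None)

    def mahalanobis_distances(self, x: np.ndarray) -> np.ndarray:
        """Mahalanobis distance from ``x`` to each class mean."""
        diff = self.class_means - np.asarray(x, dtype=float)[None, :]
        if self._cho is not None:
            sol = linalg.cho_solve(self._cho, diff.T)
        else:
            sol = self.pooled_cov_inv @ diff.T
        return np.sqrt(np.sum(diff.T * sol, axis=0))

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Equal-prior linear discriminant scores (argmax equals argmin distance)."""
        xi = self.pooled_cov_inv @ self.class_means.T  # (p, K)
        return np.asarray(x, float) @ xi - 0.5 * np.sum(self.class_means.T * xi, axis=0)


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    predicted_label: str
    distances: dict[str, float]
    nearest_distance: float


@dataclass(frozen=True)
class ScreenReport:
    feature_names: tuple[str, ...]
    f_statistics: np.ndarray
    p_values: np.ndarray
    df: tuple[int, int]
    singular_values: np.ndarray
    full_rank: bool
    wilks_lambda: float | None = None


@dataclass(frozen=True)
class MahalanobisSummary:
    """Mean +/- standard error of nearest-class-mean distance per defect group."""

    defective_mean: float | None
    defective_se: float | None
    defective_n: int
    nondefective_mean: float | None
    nondefective_se: float | None
    nondefective_n: int


def anova_f(values: Sequence[np.ndarray]) -> tuple[float, float, tuple[int, int]]:
    """One-way ANOVA F statistic, p-value and degrees of freedom.

    F = (SSB / df_b) / (SSW / df_w), with the p-value from the F
    distribution. Direct textbook computation (kept independent of
    scipy.stats.f_oneway, which the tests use as an oracle).
    """
    groups = [np.asarray(g, dtype=float) for g in values]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 records")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return float(f), p, (df_b, df_w)


def screen_features(
    records: Sequence[SampleRecord],
    group_field: str = "grade",
    feature_names: Sequence[str] = FEATURE_NAMES,
    standardised: bool = True,
) -> ScreenReport:
    """Per-feature one-way F screen plus an SVD linear-independence check.

    The F statistic for each feature uses the records grouped by
    ``group_field``; the singular values are those of the feature matrix,
    with full rank declared iff s_min > RANK_TOLERANCE * s_max.
    """
    labels = [record_label(r, group_field) for r in records]
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("need at least 2 groups")
    X = np.array([r.feature_vector(feature_names, standardised) for r in records])
    fs, ps = [], []
    df = (0, 0)
    for j in range(X.shape[1]):
        groups = [X[[i for i, l in enumerate(labels) if l == g], j] for g in unique]
        f, p, df = anova_f(groups)
        fs.append(f)
        ps.append(p)
    s = np.linalg.svd(X, compute_uv=False)
    full_rank = bool(s.size and s[-1] > RANK_TOLERANCE * s[0]) and len(s) >= X.shape[1]
    wilks = _wilks_lambda(X, labels, unique)
    return ScreenReport(
        feature_names=tuple(feature_names),
        f_statistics=np.array(fs),
        p_values=np.array(ps),
        df=df,
        singular_values=s,
        full_rank=full_rank,
        wilks_lambda=wilks,
    )


def _wilks_lambda(X: np.ndarray, labels: list[str], unique: list[str]) -> float | None:
    """Wilks' lambda det(W)/det(T); None when either matrix is singular."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in unique:
        sub = X[[i for i, l in enumerate(labels) if l == g]]
        W += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
    try:
        sign_t, logdet_t = np.linalg.slogdet(T)
        sign_w, logdet_w = np.linalg.slogdet(W)
        if sign_t <= 0 or sign_w <= 0:
            return None
        return float(np.exp(logdet_w - logdet_t))
    except np.linalg.LinAlgError:  # pragma: no cover
        return None


def fit_lda(
    records: Sequence[SampleRecord],
    feature_names: Sequence[str],
    class_labels: Sequence[str],
    target: str = "grade",
    standardised: bool = True,
) -> LDAModel:
    """Fit an LDA model: per-class means and pooled within-class covariance.

    pooled_cov = sum_k (n_k - 1) S_k / (N - K) with S_k the per-class
    sample covariance. Raises SingularCovarianceError when the pooled
    covariance cannot be Cholesky-factorised (e.g. N - K < p).
    """
    feature_names = tuple(feature_names)
    class_labels = tuple(class_labels)
    p = len(feature_names)
    by_class: dict[str, list[np.ndarray]] = {c: [] for c in class_labels}
    for r in records:
        lab = record_label(r, target)
        if lab in by_class:
            by_class[lab].append(r.feature_vector(feature_names, standardised))
    for c, rows in by_class.items():
        if len(rows) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training records")
    n_total = sum(len(rows) for rows in by_class.values())
    k = len(class_labels)
    if n_total - k < p:
        raise SingularCovarianceError(
            f"cannot fit {p} features with N-K = {n_total - k}; reduce the feature set"
        )
    means = np.array([np.mean(by_class[c], axis=0) for c in class_labels])
    pooled = np.zeros((p, p))
    for i, c in enumerate(class_labels):
        mat = np.array(by_class[c])
        dev = mat - means[i]
        pooled += dev.T @ dev
    pooled /= n_total - k
    try:
        cho = linalg.cho_factor(pooled)
        inv = linalg.cho_solve(cho, np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled within-class covariance is singular; reduce the feature set"
        ) from exc
    return LDAModel(
        feature_names=feature_names,
        class_labels=class_labels,
        class_means=means,
        pooled_cov=pooled,
        pooled_cov_inv=inv,
        _cho=cho,
    )


def classify(model: LDAModel, record: SampleRecord, standardised: bool = True) -> Prediction:
    """Assign the record to the nearest class mean in Mahalanobis distance.

    Ties are broken by the model's declared class order (argmin keeps the
    first minimum).
    """
    x = record.feature_vector(model.feature_names, standardised)
    d = model.mahalanobis_distances(x)
    i = int(np.argmin(d))
    return Prediction(
        sample_id=record.sample_id,
        predicted_label=model.class_labels[i],
        distances={c: float(d[j]) for j, c in enumerate(model.class_labels)},
        nearest_distance=float(d[i]),
    )


def classify_records(
    model: LDAModel, records: Iterable[SampleRecord], standardised: bool = True
) -> list[Prediction]:
    return [classify(model, r, standardised) for r in records]


def accuracy(
    model: LDAModel, records: Sequence[SampleRecord], target: str = "grade"
) -> float:
    """Fraction of records whose predicted label equals the true label."""
    if not records:
        raise ValueError("no records to score")
    preds = classify_records(model, records)
    hits = sum(p.predicted_label == record_label(r, target) for p, r in zip(preds, records))
    return hits / len(records)


def forward_select(
    records: Sequence[SampleRecord],
    candidates: Sequence[str],
    class_labels: Sequence[str],
    target: str = "grade",
) -> list[str]:
    """Greedy forward selection over an ordered candidate list.

    Candidates (ordered colour -> size -> shape by the caller) are tried
    one at a time; a candidate is kept iff refitting on the calibration
    records strictly increases classification accuracy on those same
    records. Candidates that make the model unfittable are skipped.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    kept: list[str] = []
    best = -np.inf
    fitted_any = False
    for cand in candidates:
        trial = kept + [cand]
        try:
            model = fit_lda(records, trial, class_labels, target)
        except (SingularCovarianceError, ValueError):
            continue
        fitted_any = True
        acc = accuracy(model, records, target)
        if acc > best:
            kept.append(cand)
            best = acc
    if not fitted_any:
        raise ValueError("no candidate feature yields a fittable model")
    return kept


def mahalanobis_summary(
    model: LDAModel, records: Sequence[SampleRecord]
) -> MahalanobisSummary:
    """Nearest-class-mean distance statistics split by the defect flag.

    Reports mean and standard error (sd / sqrt(n), ddof=1) per group;
    the SE is None for groups with fewer than 2 records, means are None
    for empty groups.
    """
    if not records:
        raise ValueError("no records")
    dists = {True: [], False: []}
    for r in records:
        pred = classify(model, r)
        dists[r.defective].append(pred.nearest_distance)

    def _stats(vals: list[float]) -> tuple[float | None, float | None, int]:
        n = len(vals)
        if n == 0:
            return None, None, 0
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else None
        return mean, se, n

    dm, dse, dn = _stats(dists[True])
    nm, nse, nn = _stats(dists[False])
    return MahalanobisSummary(dm, dse, dn, nm, nse, nn)
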