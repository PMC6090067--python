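"""Supervised template analysis of hourly SWA profiles.

The analysis asks how much information the 12-dimensional hourly SWA signal
S carries about the age/exercise class C of a mouse.  Each class c is
modelled by a multivariate normal *template* N(mu_c, Sigma_c) fitted, after
PCA reduction, on a profiling subset.  Two metrics are computed on held-out
signals:

* **Perceived information** ``PI(S;C) = H(C) - H(C|S)`` where the
  conditional entropy is evaluated with the *model* posterior
  ``Pr_model[c|s]`` (Bayes' rule over the templates) under the *true*
  distribution, sampled empirically from the test set
  (``Pr_true[s|c] = 1/n_t^c``).  PI is bounded above by H(C); it equals the
  mutual information when the templates are exact, and is degraded by model
  and estimation error.  Evaluation is leave-one-out: projection and
  templates are refit on every partition, with the held-out signal never
  touching its own fit.
* **Success rate**: fraction of held-out signals assigned to their true
  class by maximum template likelihood, under a stratified 50-50
  profile/test split.

Numerics: likelihoods are handled in log space throughout, posteriors are
normalized with log-sum-exp, and template covariances carry a ridge term so
small per-class samples stay positive-definite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.covariance import ledoit_wolf_shrinkage

from .cohort import ClassLabel, SWAProfile

#: Posteriors are floored here before taking log2, so the PI sum is finite
#: on any input.
POSTERIOR_FLOOR = 1e-300

#: Default ridge added to template covariance diagonals, as a fraction of
#: the mean diagonal element (escalated x10 until well-conditioned).
DEFAULT_RIDGE = 1e-6

#: Ridge escalation stops once eigmax/eigmin of the template covariance is
#: at most this.  Per-class samples of 4-11 points in 3 dimensions routinely
#: produce spurious near-zero eigenvalues; positive-definiteness alone
#: leaves the Gaussian density degenerate along those directions.
MAX_TEMPLATE_CONDITION = 100.0

ArrayLike = Union[np.ndarray, Sequence[SWAProfile]]


def _as_matrix(data: ArrayLike) -> Tuple[np.ndarray, Optional[List[ClassLabel]]]:
    if isinstance(data, np.ndarray):
        X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of row vectors")
        return X, None
    profiles = list(data)
    X = np.vstack([p.values for p in profiles])
    return X, [p.label for p in profiles]


@dataclass
class ProjectionModel:
    """PCA front-end: centering vector plus orthonormal loading matrix.

    Fitted only on profiling data.  Loadings are the top-``d`` principal
    directions; each column's sign is fixed so its largest-magnitude entry
    is positive, making the fit deterministic.
    """

    center: np.ndarray    # (12,)
    loadings: np.ndarray  # (12, d), orthonormal columns
    d: int
    explained_variance: np.ndarray  # (d,) eigenvalues of the sample covariance

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center) @ self.loadings


def fit_projection(data: ArrayLike, d: int) -> ProjectionModel:
    """Fit a ``d``-dimensional PCA projection on a set of profiles.

    Deterministic: directions come from the SVD of the centered matrix, with
    each loading's sign fixed by its largest-magnitude entry.
    """
    X, _ = _as_matrix(data)
    n, p = X.shape
    if not 1 <= d <= p:
        raise ValueError(f"d must be in [1, {p}], got {d}")
    if n < d + 1:
        raise ValueError(f"need at least d+1 = {d + 1} profiles, got {n}")
    center = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - center, full_matrices=False)
    loadings = vt[:d].T.copy()
    # eigenvalues of the (n-1)-denominator sample covariance
    ev = (s[:d] ** 2) / (n - 1)
    for j in range(d):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return ProjectionModel(center=center, loadings=loadings, d=d, explained_variance=ev)


@dataclass
class ClassTemplate:
    """Multivariate-normal model of one class in projected space."""

    label: Optional[ClassLabel]
    mean: np.ndarray  # (d,)
    cov: np.ndarray   # (d, d), symmetric positive-definite after ridge
    n: int            # training count

    def log_likelihood(self, z: np.ndarray) -> np.ndarray:
        return multivariate_normal(self.mean, self.cov).logpdf(z)


def fit_template(
    data: ArrayLike,
    projection: ProjectionModel,
    regularization: float = DEFAULT_RIDGE,
    max_condition: float = MAX_TEMPLATE_CONDITION,
    shrinkage: Optional[str] = "ledoit-wolf",
) -> ClassTemplate:
    """Estimate one class template from its profiling subset.

    Starts from the projected sample mean and sample covariance (n-1
    denominator).  By default the covariance is shrunk toward its spherical
    target with the Ledoit-Wolf intensity estimated from the same data
    (``shrinkage="ledoit-wolf"``): with the per-class sample sizes this
    analysis sees (4-11 points in 3 dimensions) the raw sample covariance's
    smallest eigenvalue is severely biased downward, which makes a pure
    maximum-likelihood template reject its own class's signals.
    ``shrinkage=None`` keeps the raw sample covariance.  In either case a
    diagonal ridge of ``regularization * mean(diag)`` is added, escalated by
    factors of 10 until the covariance is positive-definite and its
    condition number is at most ``max_condition``.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if max_condition < 1:
        raise ValueError("max_condition must be >= 1")
    if shrinkage not in (None, "ledoit-wolf"):
        raise ValueError("shrinkage must be 'ledoit-wolf' or None")
    X, labels = _as_matrix(data)
    if labels is not None and len(set(labels)) > 1:
        raise ValueError("fit_template expects profiles from a single class")
    n = X.shape[0]
    if n < 2:
        raise ValueError("a class template needs at least 2 profiles")
    Z = projection.transform(X)
    mean = Z.mean(axis=0)
    cov = np.atleast_2d(np.cov(Z, rowvar=False, ddof=1))
    if shrinkage == "ledoit-wolf" and np.trace(cov) > 0:
        lam = float(ledoit_wolf_shrinkage(Z))
        target = np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        cov = (1 - lam) * cov + lam * target
    base = float(np.mean(np.diag(cov)))
    if base <= 0:
        base = 1.0
    ridge = regularization * base
    eye = np.eye(projection.d)
    eigs = np.linalg.eigvalsh(cov)
    for _ in range(60):
        lo, hi = eigs[0] + ridge, eigs[-1] + ridge
        if lo > 0 and hi <= max_condition * lo:
            break
        ridge *= 10
    else:  # pragma: no cover - only reachable with pathological input
        raise np.linalg.LinAlgError("could not regularize covariance to positive-definite")
    lab = labels[0] if labels else None
    return ClassTemplate(label=lab, mean=mean, cov=cov + ridge * eye, n=n)


def posterior(
    z: np.ndarray,
    templates: Sequence[ClassTemplate],
    priors: np.ndarray,
) -> np.ndarray:
    """Model posterior over classes for one projected signal (Bayes' rule).

    Computed in log space with log-sum-exp normalization, so simultaneous
    density underflow never divides by zero.  Returns a probability vector
    aligned with ``templates``.
    """
    priors = np.asarray(priors, dtype=float)
    if len(priors) != len(templates):
        raise ValueError("priors must align with templates")
    if abs(priors.sum() - 1.0) > 1e-9 or np.any(priors < 0):
        raise ValueError("priors must be a probability vector")
    with np.errstate(divide="ignore"):
        logp = np.array(
            [float(t.log_likelihood(z)) for t in templates]
        ) + np.log(priors)
    return np.exp(logp - logsumexp(logp))


@dataclass
class PIResult:
    """Perceived-information estimate with its cross-validation trace."""

    pi: float                          # bits
    partition_values: np.ndarray       # per-LOO-partition PI values, bits
    bootstrap_ci: Tuple[float, float]  # percentile (5%, 95%) of resample means
    priors: Dict[str, float]           # class prior actually used
    class_entropy: float               # H(C), bits

    def to_dict(self) -> dict:
        return {
            "pi_bits": self.pi,
            "class_entropy_bits": self.class_entropy,
            "bootstrap_ci_bits": list(self.bootstrap_ci),
            "priors": self.priors,
            "partition_values_bits": [float(v) for v in self.partition_values],
        }


def _prior_vector(
    classes: Sequence[ClassLabel], counts: Dict[ClassLabel, int], policy: str
) -> np.ndarray:
    if policy == "uniform":
        return np.full(len(classes), 1.0 / len(classes))
    if policy == "empirical":
        total = sum(counts.values())
        return np.array([counts[c] / total for c in classes])
    raise ValueError(f"unknown priors policy {policy!r} (use 'uniform' or 'empirical')")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def perceived_information(
    profiles: Sequence[SWAProfile],
    d: int = 3,
    priors: str = "uniform",
    regularization: float = DEFAULT_RIDGE,
    max_condition: float = MAX_TEMPLATE_CONDITION,
    shrinkage: Optional[str] = "ledoit-wolf",
    n_bootstrap: int = 100,
    seed: int = 0,
) -> PIResult:
    """Leave-one-out perceived information between SWA and class, in bits.

    For each held-out signal, the projection and all class templates are
    refit on the remaining signals (no leakage), and the log2 model
    posterior of the held-out signal's true class is recorded.  Pooling all
    leave-one-out rounds, each class's test set is visited exactly n_c
    times, so ``Pr_true[s|c] = 1/n_c`` and

        PI = H(C) + sum_c Pr[c] * (1/n_c) * sum_{s in c} log2 Pr_model[c|s].

    This pooled sum is reported as the mean of per-partition values
    ``H(C) + (N * Pr[c_i] / n_{c_i}) * log2 Pr_model[c_i|s_i]``, whose
    spread feeds the percentile bootstrap: ``n_bootstrap`` resamples of the
    partition values (with replacement), CI endpoints at the 5th and 95th
    percentiles of the resample means.
    """
    X, labels = _as_matrix(profiles)
    if labels is None:
        raise ValueError("perceived_information needs labelled SWAProfile inputs")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = {c: labels.count(c) for c in classes}
    small = [c.short for c in classes if counts[c] < 3]
    if small:
        raise ValueError(f"every class needs >= 3 profiles for leave-one-out; too few in {small}")

    prior = _prior_vector(classes, counts, priors)
    h_c = _entropy_bits(prior)
    n_total = len(labels)
    class_index = {c: j for j, c in enumerate(classes)}
    label_idx = np.array([class_index[lab] for lab in labels])

    values = np.empty(n_total)
    for i in range(n_total):
        rest = np.ones(n_total, dtype=bool)
        rest[i] = False
        proj = fit_projection(X[rest], d)
        templates = [
            fit_template(X[rest & (label_idx == j)], proj, regularization,
                         max_condition, shrinkage)
            for j in range(len(classes))
        ]
        post = posterior(proj.transform(X[i]), templates, prior)
        j = label_idx[i]
        p_true = max(float(post[j]), POSTERIOR_FLOOR)
        weight = n_total * prior[j] / counts[classes[j]]
        values[i] = h_c + weight * math.log2(p_true)

    # each partition value is <= H(C) exactly; guard the mean against the
    # one-ulp float drift of summing many equal terms
    pi = min(float(values.mean()), h_c)
    rng = np.random.default_rng(seed)
    boot_means = np.array(
        [rng.choice(values, size=n_total, replace=True).mean() for _ in range(n_bootstrap)]
    )
    ci = (float(np.percentile(boot_means, 5)), float(np.percentile(boot_means, 95)))
    return PIResult(
        pi=pi,
        partition_values=values,
        bootstrap_ci=ci,
        priors={c.short: float(p) for c, p in zip(classes, prior)},
        class_entropy=h_c,
    )


@dataclass
class ClassificationReport:
    """Outcome of template / maximum-likelihood classification."""

    classes: Tuple[ClassLabel, ...]
    true_labels: List[ClassLabel]
    predicted_labels: List[ClassLabel]
    confusion: np.ndarray  # (m, m) counts, rows true, columns predicted
    success_rate: float    # trace / total

    def to_dict(self) -> dict:
        return {
            "classes": [c.short for c in self.classes],
            "success_rate": self.success_rate,
            "confusion": self.confusion.tolist(),
            "true_labels": [c.short for c in self.true_labels],
            "predicted_labels": [c.short for c in self.predicted_labels],
        }


def _stratified_split(
    members: List[int], seed: int, repeat: int
) -> Tuple[List[int], List[int]]:
    # The split stream is keyed by the class's member row indices (not the
    # label), so relabelling groups permutes reports without changing splits.
    rng = np.random.default_rng([seed, repeat, *members])
    order = [members[k] for k in rng.permutation(len(members))]
    n_profile = math.ceil(len(members) / 2)
    return order[:n_profile], order[n_profile:]


def success_rate(
    profiles: Sequence[SWAProfile],
    d: int = 3,
    regularization: float = DEFAULT_RIDGE,
    max_condition: float = MAX_TEMPLATE_CONDITION,
    shrinkage: Optional[str] = "ledoit-wolf",
    seed: int = 0,
    repeats: int = 1,
) -> ClassificationReport:
    """Template classification under a stratified 50-50 profile/test split.

    Each class is split (seeded) into ceil(n/2) profiling and floor(n/2)
    test signals; templates are fitted on the pooled profiling halves and
    every test signal is assigned to the class with maximal template
    likelihood.  Exact likelihood ties go to the lowest class index (with a
    warning).  ``repeats > 1`` accumulates several seeded splits into one
    confusion matrix.
    """
    X, labels = _as_matrix(profiles)
    if labels is None:
        raise ValueError("success_rate needs labelled SWAProfile inputs")
    classes = tuple(sorted(set(labels)))
    counts = {c: labels.count(c) for c in classes}
    small = [c.short for c in classes if counts[c] < 4]
    if small:
        raise ValueError(f"every class needs >= 4 profiles for a 50-50 split; too few in {small}")
    class_index = {c: j for j, c in enumerate(classes)}
    members = {c: [i for i, lab in enumerate(labels) if lab == c] for c in classes}

    m = len(classes)
    confusion = np.zeros((m, m), dtype=int)
    y_true: List[ClassLabel] = []
    y_pred: List[ClassLabel] = []
    for r in range(repeats):
        profile_idx: List[int] = []
        test_idx: List[int] = []
        for c in classes:
            p_idx, t_idx = _stratified_split(members[c], seed, r)
            profile_idx.extend(p_idx)
            test_idx.extend(t_idx)
        proj = fit_projection(X[profile_idx], d)
        templates = [
            fit_template(
                X[[i for i in profile_idx if labels[i] == c]], proj,
                regularization, max_condition, shrinkage,
            )
            for c in classes
        ]
        Z = proj.transform(X[test_idx])
        loglik = np.column_stack([t.log_likelihood(Z) for t in templates])
        for row, i in zip(loglik, test_idx):
            best = int(np.argmax(row))
            if np.sum(row == row[best]) > 1:
                warnings.warn(
                    f"likelihood tie for signal {i}; assigned to lowest class index",
                    stacklevel=2,
                )
            confusion[class_index[labels[i]], best] += 1
            y_true.append(labels[i])
            y_pred.append(classes[best])

    total = int(confusion.sum())
    rate = float(np.trace(confusion)) / total
    return ClassificationReport(
        classes=classes,
        true_labels=y_true,
        predicted_labels=y_pred,
        confusion=confusion,
        success_rate=rate,
    )
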