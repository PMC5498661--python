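"""Zero-mean Gaussian covariance classification of brain states.

Because the recordings are z-scored, each state is fully characterised (in
the Gaussian approximation) by its spatial covariance.  A held-out
recording X (N x T) is assigned to the state whose training covariance
maximises the log-likelihood

    L(X | Sigma) = -T/2 * (N log 2pi + log det Sigma)
                   - 1/2 * sum_t X_t' Sigma^{-1} X_t,

with time points treated as independent.  Cross-validation is jackknife
(leave one subject out); chance level for n binary tests follows the
Binomial(n, 1/2) tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .containers import RoiTimeSeries
from .exceptions import DesignError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianModel",
    "ClassificationReport",
    "SimilarityEntry",
    "fit_gaussian",
    "log_likelihood",
    "jackknife_classify",
    "chance_threshold",
    "similarity_ratio",
]


@dataclass
class GaussianModel:
    """Zero-mean multivariate Gaussian: covariance, Cholesky factor and
    log-determinant.  Likelihoods are computed through linear solves, never
    through the raw determinant."""

    sigma: np.ndarray
    cho: tuple
    log_det: float
    ridge: float = 0.0

    @property
    def n(self) -> int:
        return self.sigma.shape[0]


def _fit_cov(X: np.ndarray) -> GaussianModel:
    """Zero-mean sample covariance of an N x T data matrix, with a minimal
    ridge added only when the covariance is not positive definite."""
    n, t = X.shape
    sigma = (X @ X.T) / t
    ridge = 0.0
    eigmin = linalg.eigvalsh(sigma, subset_by_index=(0, 0))[0]
    if eigmin <= 0.0:
        ridge = abs(eigmin) + 1e-10 * max(1.0, np.trace(sigma) / n)
        sigma = sigma + ridge * np.eye(n)
        logger.info("covariance not positive definite; added ridge %.3e", ridge)
    cho = linalg.cho_factor(sigma, lower=True)
    log_det = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return GaussianModel(sigma=sigma, cho=cho, log_det=log_det, ridge=ridge)


def fit_gaussian(train: list[RoiTimeSeries]) -> GaussianModel:
    """Fit the state covariance from the time-wise concatenation of all
    training recordings (which are assumed z-scored, hence zero mean)."""
    if not train:
        raise DesignError("empty train set")
    n = train[0].n_rois
    if any(ts.n_rois != n for ts in train):
        raise ShapeError("training recordings have inconsistent ROI counts")
    X = np.hstack([ts.data for ts in train])
    return _fit_cov(X)


def log_likelihood(x: RoiTimeSeries | np.ndarray, model: GaussianModel) -> float:
    """Log-likelihood of an N x T recording under the zero-mean Gaussian."""
    data = x.data if isinstance(x, RoiTimeSeries) else np.asarray(x, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n, t = data.shape
    if n != model.n:
        raise ShapeError(f"dimension mismatch: data has {n} ROIs, model {model.n}")
    solved = linalg.cho_solve(model.cho, data)
    quad = float(np.sum(data * solved))
    return -0.5 * (t * (n * np.log(2.0 * np.pi) + model.log_det) + quad)


@dataclass
class ClassificationReport:
    """Jackknife classification outcome.

    ``records`` holds one (subject, true_state, predicted_state) triple per
    tested recording; accuracies are per true state, over the n folds.
    """

    records: list[tuple[str, str, str]]
    per_state_accuracy: dict[str, float]
    n_subjects: int
    chance_threshold: float = float("nan")
    ties: int = 0


def jackknife_classify(cohort, alpha: float = 0.05) -> ClassificationReport:
    """Leave-one-subject-out Gaussian classification of a paired cohort.

    For each held-out subject, both state covariances are fitted on the
    remaining subjects; each of the held-out subject's two recordings is
    assigned to the state with the larger log-likelihood.  Exact ties are
    broken toward the second state in sorted label order (for awake/sleep
    labels: sleep) and counted in the report.
    """
    from .inference import _as_recordings, _paired_by_subject

    recordings = _as_recordings(cohort)
    states, by_subject = _paired_by_subject(recordings)
    subjects = sorted(by_subject)
    if len(subjects) < 3:
        raise DesignError("jackknife classification needs at least 3 subjects")

    records: list[tuple[str, str, str]] = []
    ties = 0
    for held in subjects:
        try:
            models = {
                s: fit_gaussian([by_subject[o][s] for o in subjects if o != held])
                for s in states
            }
        except Exception as exc:
            raise DesignError(f"covariance fit failed in fold for subject {held!r}") from exc
        for true_state in states:
            ts = by_subject[held][true_state]
            ll = {s: log_likelihood(ts, models[s]) for s in states}
            if ll[states[0]] > ll[states[1]]:
                predicted = states[0]
            elif ll[states[1]] > ll[states[0]]:
                predicted = states[1]
            else:
                predicted = states[1]
                ties += 1
                logger.info("likelihood tie for subject %s; predicting %s", held, predicted)
            records.append((held, true_state, predicted))

    accuracy = {
        s: float(np.mean([r[2] == s for r in records if r[1] == s])) for s in states
    }
    k = chance_threshold(len(subjects), alpha)
    chance = k / len(subjects) if k is not None else float("nan")
    return ClassificationReport(
        records=records,
        per_state_accuracy=accuracy,
        n_subjects=len(subjects),
        chance_threshold=chance,
        ties=ties,
    )


def chance_threshold(n: int, alpha: float = 0.05) -> int | None:
    """Smallest hit count k with P(X >= k) < alpha under Binomial(n, 1/2).

    Returns None when no k <= n achieves significance (e.g. n = 1 at
    alpha = 0.05).
    """
    if n < 1:
        raise ShapeError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ShapeError("alpha must lie in (0, 1)")
    for k in range(n + 1):
        # P(X >= k) = sf(k - 1)
        if stats.binom.sf(k - 1, n, 0.5) < alpha:
            return k
    return None


@dataclass
class SimilarityEntry:
    """Mean log-likelihood ratio <r_i> of one subject against pseudo-series
    resampled from the pooled group data, with its resampling SD."""

    subject: str
    state: str
    mean_ratio: float
    sd_ratio: float
    n_resamples: int


def similarity_ratio(
    cohort,
    subject: str,
    state: str,
    n_resamples: int = 50,
    seed: int = 0,
) -> SimilarityEntry:
    """Log-likelihood-ratio similarity of one subject to the group.

    Per resample: pool the other subjects' recordings (same state) along
    time, randomly exclude T column vectors to form a pseudo-series
    X_pseudo, fit the covariance on the remaining columns, and compute
    r = L(X_i | Sigma) / L(X_pseudo | Sigma).  <r_i> near 1 indicates the
    subject is indistinguishable from a random sample of the group.
    """
    from .inference import _as_recordings

    recordings = _as_recordings(cohort)
    target = [ts for ts in recordings if ts.subject == subject and ts.state == state]
    if not target:
        raise DesignError(f"subject {subject!r} with state {state!r} not found")
    x_i = target[0].data
    n, t = x_i.shape
    others = [
        ts.data for ts in recordings if ts.subject != subject and ts.state == state
    ]
    if not others:
        raise DesignError("no other subjects to pool")
    pool = np.hstack(others)
    m = pool.shape[1]
    if m - t < n + 2:
        raise DesignError(
            f"pooled data too short: {m} columns, need > {t + n + 2} to exclude T vectors"
        )
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_resamples)
    for k in range(n_resamples):
        idx = rng.choice(m, size=t, replace=False)
        mask = np.ones(m, dtype=bool)
        mask[idx] = False
        model = _fit_cov(pool[:, mask])
        l_subj = log_likelihood(x_i, model)
        l_pseudo = log_likelihood(pool[:, idx], model)
        ratios[k] = l_subj / l_pseudo
    return SimilarityEntry(
        subject=subject,
        state=state,
        mean_ratio=float(ratios.mean()),
        sd_ratio=float(ratios.std()),
        n_resamples=n_resamples,
    )
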