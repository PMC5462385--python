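"""Latent class growth analysis (LCGA) for longitudinal bounded scores.

A K-class LCGA is a finite mixture of quadratic growth curves: subject i in
class k has

    y_it = b0k + b1k * t*_it + b2k * t*_it^2 + e_it,   e_it ~ N(0, sigma_k^2)

with t* = t - time_center and no within-class random effects. The subject
(not the observation) is the mixture unit: all of a subject's scores share
one latent class. Fitting is by EM with subject-level responsibilities;
the M-step is responsibility-weighted least squares per class. Model
comparison uses AIC/BIC (BIC on the observation count), the relative
entropy of the posterior classification, and a parametric bootstrapped
likelihood ratio test (BLRT) for k versus k-1 classes.

Each full K-class model carries 5K - 1 free parameters: three growth
coefficients and one residual SD per class plus K - 1 free mixing
proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthMixtureModel",
    "FitResult",
    "BlrtResult",
    "ModelSelectionRow",
    "subject_loglik",
    "fit_lcga",
    "relative_entropy",
    "assign_classes",
    "simulate_from_model",
    "blrt",
    "model_selection_sweep",
]

#: residual SDs are clamped below at this value (MMSE points) so a class
#: shrinking onto identical scores cannot blow up the likelihood
SIGMA_FLOOR = 0.1


@dataclass
class GrowthMixtureModel:
    """Fitted (or generating) K-class quadratic growth mixture."""

    beta: np.ndarray  # (K, 3): intercept, linear, quadratic on centered time
    sigma: np.ndarray  # (K,) residual SD, MMSE points
    pi: np.ndarray  # (K,) mixing proportions
    time_center: float  # years; t* = t - time_center

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.pi)

    def mean_trajectory(self, k: int, times: np.ndarray) -> np.ndarray:
        """Class-k mean score at raw times (1-based class label)."""
        t = np.asarray(times, dtype=float) - self.time_center
        b = self.beta[k - 1]
        return b[0] + b[1] * t + b[2] * t * t


@dataclass
class FitResult:
    """An LCGA fit with model-selection statistics and posteriors."""

    model: GrowthMixtureModel
    loglik: float
    n_obs: int
    n_subjects: int
    n_params: int
    aic: float
    bic: float
    eic: float | None  # undefined for K=1
    posteriors: pd.DataFrame  # n_subjects x K, rows sum to 1
    coefficient_se: np.ndarray  # (K, 3)
    iterations: int
    converged: bool
    k_effective: int


@dataclass
class BlrtResult:
    """Parametric bootstrap LRT of k_alt classes against k_null = k_alt - 1."""

    k_null: int
    k_alt: int
    observed_lr: float
    bootstrap_lrs: np.ndarray
    p_value: float


@dataclass
class ModelSelectionRow:
    k_specified: int
    iterations: int
    k_effective: int
    loglik: float
    aic: float
    bic: float
    eic: float | None
    blrt_p: float | None


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------


def _prepare(scores: pd.DataFrame):
    """Clean-score table -> (subject ids, codes, times, values)."""
    sid = scores["subject_id"].to_numpy()
    subjects, codes = np.unique(sid, return_inverse=True)
    t = scores["time_years"].to_numpy(dtype=float)
    y = scores["weighted_score"].to_numpy(dtype=float)
    return subjects, codes, t, y


def _design(t: np.ndarray, time_center: float) -> np.ndarray:
    ts = t - time_center
    return np.column_stack([np.ones_like(ts), ts, ts * ts])


def _obs_log_density(X, y, beta, sigma):
    """(n_obs, K) Gaussian log-densities of each score under each class."""
    mu = X @ beta.T
    resid = y[:, None] - mu
    return -0.5 * np.log(2 * np.pi * sigma**2)[None, :] - resid**2 / (
        2 * sigma**2
    )[None, :]


def _subject_sums(values: np.ndarray, codes: np.ndarray, n_subjects: int):
    """Sum an (n_obs, K) array within subjects -> (n_subjects, K)."""
    K = values.shape[1]
    out = np.empty((n_subjects, K))
    for k in range(K):
        out[:, k] = np.bincount(codes, weights=values[:, k], minlength=n_subjects)
    return out


def subject_loglik(model: GrowthMixtureModel, scores: pd.DataFrame) -> float:
    """Mixture log-likelihood contribution of a single subject.

    ln sum_k pi_k prod_t N(y_t; mu_k(t*), sigma_k^2), evaluated with a
    log-sum-exp over classes for numerical stability.
    """
    if scores.empty:
        raise ValueError("subject has no scores")
    t = scores["time_years"].to_numpy(dtype=float)
    y = scores["weighted_score"].to_numpy(dtype=float)
    X = _design(t, model.time_center)
    ld = _obs_log_density(X, y, model.beta, model.sigma).sum(axis=0)
    with np.errstate(divide="ignore"):  # pi entries of exactly 0 are allowed here
        return float(logsumexp(ld + np.log(model.pi)))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _m_step(X, y, codes, R, sigma_floor):
    """Responsibility-weighted least squares per class.

    Returns (beta, sigma, pi, xtwx_per_class); sigma is clamped at the floor.
    """
    n_subjects, K = R.shape
    beta = np.empty((K, 3))
    sigma = np.empty(K)
    xtwx = []
    W = R[codes]  # (n_obs, K) observation weights
    for k in range(K):
        w = W[:, k]
        Xw = X * w[:, None]
        G = X.T @ Xw
        beta[k] = np.linalg.solve(G, X.T @ (w * y))
        resid = y - X @ beta[k]
        sigma[k] = np.sqrt(max((w * resid**2).sum() / w.sum(), sigma_floor**2))
        xtwx.append(G)
    pi = R.mean(axis=0)
    return beta, sigma, pi, xtwx


def _e_step(X, y, codes, n_subjects, beta, sigma, pi):
    ld = _obs_log_density(X, y, beta, sigma)
    S = _subject_sums(ld, codes, n_subjects) + np.log(pi)[None, :]
    norm = logsumexp(S, axis=1)
    R = np.exp(S - norm[:, None])
    return float(norm.sum()), R


def _subject_summaries(X, y, codes, n_subjects):
    """Per-subject least-squares (level, slope) on centered time.

    Closed-form 2-parameter fit from within-subject sums; subjects with a
    degenerate time spread fall back to slope 0.
    """
    ones = np.ones_like(y)
    n = np.bincount(codes, weights=ones, minlength=n_subjects)
    st = np.bincount(codes, weights=X[:, 1], minlength=n_subjects)
    sy = np.bincount(codes, weights=y, minlength=n_subjects)
    stt = np.bincount(codes, weights=X[:, 1] ** 2, minlength=n_subjects)
    sty = np.bincount(codes, weights=X[:, 1] * y, minlength=n_subjects)
    det = n * stt - st**2
    safe = det > 1e-10
    slope = np.zeros(n_subjects)
    slope[safe] = (n[safe] * sty[safe] - st[safe] * sy[safe]) / det[safe]
    level = (sy - slope * st) / n
    return np.column_stack([level, slope])


def _init_responsibilities(kind, k, n_subjects, rng, summaries):
    if k == 1:
        return np.ones((n_subjects, 1))
    if kind == "dirichlet":
        return rng.dirichlet(np.ones(k), size=n_subjects)
    # k-means on standardized per-subject (level, slope), soft-coded 0.9/0.1
    from scipy.cluster.vq import kmeans2

    Z = (summaries - summaries.mean(0)) / (summaries.std(0) + 1e-12)
    _, labels = kmeans2(Z, k, minit="++", seed=rng)
    R = np.full((n_subjects, k), 0.1 / k)
    R[np.arange(n_subjects), labels] += 0.9
    return R


def fit_lcga(
    scores: pd.DataFrame,
    k: int,
    restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    sigma_floor: float = SIGMA_FLOOR,
    time_center: float | None = None,
    init: str = "kmeans",
) -> FitResult:
    """Fit a k-class LCGA by EM over random restarts.

    Each restart initializes subject responsibilities from a randomized
    k-means partition of per-subject (level, slope) least-squares summaries
    (``init="dirichlet"`` draws them from a symmetric Dirichlet(1) instead);
    the restart with the best final log-likelihood wins. The time-centering
    constant defaults to the mean observation time and is stored on the
    model. Classes are relabeled in strictly descending order of fitted
    intercept. A class whose mixing proportion falls below 1/n_subjects is
    removed (the fit continues with fewer classes), so ``k_effective`` may
    be smaller than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    subjects, codes, t, y = _prepare(scores)
    n_subjects = len(subjects)
    n_obs = len(y)
    if n_subjects == 0:
        raise ValueError("no subjects in cohort")
    if time_center is None:
        time_center = float(t.mean())
    X = _design(t, time_center)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    summaries = _subject_summaries(X, y, codes, n_subjects) if k > 1 else None

    best = None
    for _ in range(max(restarts, 1) if k > 1 else 1):
        R = _init_responsibilities(init, k, n_subjects, rng, summaries)
        beta = sigma = pi = None
        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        it = 0
        while it < max_iter:
            it += 1
            beta, sigma, pi, _ = _m_step(X, y, codes, R, sigma_floor)
            # degeneracy: drop classes whose share collapses
            alive = pi >= 1.0 / n_subjects
            if not alive.all():
                beta, sigma, pi = beta[alive], sigma[alive], pi[alive] / pi[alive].sum()
                prev_ll = -np.inf  # likelihood is not comparable across k
            ll, R = _e_step(X, y, codes, n_subjects, beta, sigma, pi)
            if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
                raise RuntimeError(
                    f"EM log-likelihood decreased: {prev_ll:.6f} -> {ll:.6f}"
                )
            if np.isfinite(prev_ll) and ll - prev_ll < tol * abs(ll):
                converged = True
                break
            prev_ll = ll
        if best is None or ll > best[0]:
            best = (ll, beta, sigma, pi, R, it, converged)

    ll, beta, sigma, pi, R, iterations, converged = best
    if not converged:
        logger.warning("EM did not converge in %d iterations (k=%d)", max_iter, k)

    # canonical labels: descending intercept
    order = np.argsort(-beta[:, 0], kind="stable")
    beta, sigma, pi, R = beta[order], sigma[order], pi[order], R[:, order]
    k_eff = len(pi)

    # coefficient SEs from the weighted least-squares covariance at convergence
    W = R[codes]
    se = np.empty_like(beta)
    for j in range(k_eff):
        G = X.T @ (X * W[:, j][:, None])
        se[j] = np.sqrt(np.diag(np.linalg.inv(G)) * sigma[j] ** 2)

    n_params = 5 * k_eff - 1
    aic = -2 * ll + 2 * n_params
    bic = -2 * ll + n_params * np.log(n_obs)
    eic = relative_entropy(R) if k_eff >= 2 else None
    model = GrowthMixtureModel(beta=beta, sigma=sigma, pi=pi, time_center=time_center)
    posteriors = pd.DataFrame(
        R, index=pd.Index(subjects, name="subject_id"), columns=range(1, k_eff + 1)
    )
    return FitResult(
        model=model,
        loglik=float(ll),
        n_obs=n_obs,
        n_subjects=n_subjects,
        n_params=n_params,
        aic=float(aic),
        bic=float(bic),
        eic=eic,
        posteriors=posteriors,
        coefficient_se=se,
        iterations=iterations,
        converged=converged,
        k_effective=k_eff,
    )


# ---------------------------------------------------------------------------
# Classification quality and assignment
# ---------------------------------------------------------------------------


def relative_entropy(posteriors) -> float:
    """Relative entropy (entropy information criterion) of a classification.

    EIC = 1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K), with 0 ln 0 = 0.
    1 means perfectly separated classes; 0 means uninformative posteriors.
    Undefined for K = 1.
    """
    P = np.asarray(posteriors, dtype=float)
    n, K = P.shape
    if K < 2:
        raise ValueError("relative entropy is undefined for K = 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


def assign_classes(fit: FitResult) -> pd.DataFrame:
    """Maximum-posterior class per subject (ties to the lower class label).

    Returns the hard assignment alongside the full posterior row, which the
    posterior-weighted sensitivity analysis reuses.
    """
    P = fit.posteriors
    hard = P.to_numpy().argmax(axis=1) + 1  # argmax takes the first max: lower label
    out = P.copy()
    out.insert(0, "assigned_class", hard)
    return out


# ---------------------------------------------------------------------------
# Parametric bootstrap LRT
# ---------------------------------------------------------------------------


def simulate_from_model(
    model: GrowthMixtureModel,
    subject_times: list[np.ndarray],
    rng: np.random.Generator,
    subject_ids=None,
) -> pd.DataFrame:
    """Draw a cohort from a fitted model on given per-subject time grids."""
    n = len(subject_times)
    labels = rng.choice(model.n_classes, size=n, p=model.pi)
    if subject_ids is None:
        subject_ids = [f"B{i:05d}" for i in range(n)]
    rows_sid, rows_t, rows_y = [], [], []
    for i, times in enumerate(subject_times):
        k = labels[i]
        mu = model.mean_trajectory(k + 1, times)
        yv = mu + rng.normal(0.0, model.sigma[k], size=len(times))
        rows_sid.extend([subject_ids[i]] * len(times))
        rows_t.extend(times)
        rows_y.extend(yv)
    return pd.DataFrame(
        {"subject_id": rows_sid, "time_years": rows_t, "weighted_score": rows_y}
    )


def blrt(
    scores: pd.DataFrame,
    k: int,
    B: int = 99,
    seed: int | np.random.Generator | None = None,
    restarts: int = 20,
    bootstrap_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    fit_null: FitResult | None = None,
    fit_alt: FitResult | None = None,
) -> BlrtResult:
    """Bootstrapped likelihood ratio test of k classes against k - 1.

    The observed statistic is 2(loglik_k - loglik_{k-1}). Its null
    distribution is built by refitting both models to B cohorts simulated
    from the fitted (k-1)-class model on the observed per-subject time
    grids; p = (1 + #{bootstrap LR >= observed LR}) / (B + 1).
    """
    if k < 2:
        raise ValueError("BLRT needs k >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fit_null is None:
        fit_null = fit_lcga(scores, k - 1, restarts=restarts, tol=tol,
                            max_iter=max_iter, seed=rng)
    if fit_alt is None:
        fit_alt = fit_lcga(scores, k, restarts=restarts, tol=tol,
                           max_iter=max_iter, seed=rng)
    lr = 2 * (fit_alt.loglik - fit_null.loglik)
    if lr < 0:
        logger.warning(
            "observed LR negative (%.3f): k-model at a worse local optimum; clamping to 0",
            lr,
        )
        lr = 0.0

    times_by_subject = [
        g.to_numpy(dtype=float)
        for _, g in pd.Series(
            scores["time_years"].to_numpy(), index=scores["subject_id"].to_numpy()
        ).groupby(level=0)
    ]
    boot = np.empty(B)
    for b in range(B):
        sim = simulate_from_model(fit_null.model, times_by_subject, rng)
        f0 = fit_lcga(sim, k - 1, restarts=bootstrap_restarts, tol=tol,
                      max_iter=max_iter, seed=rng,
                      time_center=fit_null.model.time_center)
        f1 = fit_lcga(sim, k, restarts=bootstrap_restarts, tol=tol,
                      max_iter=max_iter, seed=rng,
                      time_center=fit_null.model.time_center)
        boot[b] = max(0.0, 2 * (f1.loglik - f0.loglik))
    p = (1 + int((boot >= lr).sum())) / (B + 1)
    return BlrtResult(
        k_null=k - 1, k_alt=k, observed_lr=lr, bootstrap_lrs=boot, p_value=p
    )


# ---------------------------------------------------------------------------
# Model selection sweep
# ---------------------------------------------------------------------------


def model_selection_sweep(
    scores: pd.DataFrame,
    k_max: int,
    B: int = 99,
    seed: int | None = None,
    restarts: int = 20,
    bootstrap_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    stop_early: bool = False,
) -> tuple[list[ModelSelectionRow], int, dict]:
    """Fit k = 1..k_max, run BLRTs, and select the number of classes.

    Selection is sequential: walking up from k = 2, the selected k is the
    largest whose BLRT p-value is below 0.05 before the first non-significant
    step (which ends the sequence). This keeps a model with fewer classes
    even when BIC keeps falling for larger k. With ``stop_early`` the sweep
    stops fitting past the first non-significant BLRT; otherwise all rows up
    to ``k_max`` are produced.

    Returns (rows, selected_k, fits-by-k).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    rng = np.random.default_rng(seed)
    fits: dict[int, FitResult] = {}
    rows: list[ModelSelectionRow] = []
    selected = 1
    sequence_alive = True
    for k in range(1, k_max + 1):
        fits[k] = fit_lcga(scores, k, restarts=restarts, tol=tol,
                           max_iter=max_iter, seed=rng)
        f = fits[k]
        p = None
        if k >= 2:
            res = blrt(
                scores, k, B=B, seed=rng, bootstrap_restarts=bootstrap_restarts,
                tol=tol, max_iter=max_iter,
                fit_null=fits[k - 1], fit_alt=f,
            )
            p = res.p_value
            if sequence_alive:
                if p < 0.05:
                    selected = k
                else:
                    sequence_alive = False
        rows.append(
            ModelSelectionRow(
                k_specified=k,
                iterations=f.iterations,
                k_effective=f.k_effective,
                loglik=f.loglik,
                aic=f.aic,
                bic=f.bic,
                eic=f.eic,
                blrt_p=p,
            )
        )
        if stop_early and not sequence_alive:
            break
    return rows, selected, fits


def sweep_to_frame(rows: list[ModelSelectionRow]) -> pd.DataFrame:
    """Model-selection rows as a table (one row per k specified)."""
    return pd.DataFrame(
        [
            {
                "k_specified": r.k_specified,
                "iter": r.iterations,
                "k": r.k_effective,
                "logLik": r.loglik,
                "AIC": r.aic,
                "BIC": r.bic,
                "EIC": r.eic,
                "BLRT_p": r.blrt_p,
            }
            for r in rows
        ]
    )
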