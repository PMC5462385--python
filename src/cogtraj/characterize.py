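"""Characterisation of trajectory classes by baseline covariates.

Two stages: (1) global association screens — Kruskal–Wallis for continuous
variables, Pearson chi-square for categorical ones, switching to Fisher's
exact test (Monte Carlo for tables beyond 2x2) when expected cell counts
fall below 5; (2) a multivariable multinomial logistic regression of class
membership on baseline covariates relative to a reference trajectory, with
backward stepwise selection over variable blocks by AIC,
Benjamini–Hochberg-adjusted p-values, and false-coverage-rate (FCR)
adjusted Wald confidence intervals for the selected coefficients.

The multinomial likelihood is maximised by Newton iterations with analytic
gradient and Hessian; per-row weights support the posterior-weighted
sensitivity fit, in which each subject contributes one pseudo-observation
per class weighted by its posterior membership probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTestResult",
    "MultinomialModel",
    "global_association_tests",
    "monte_carlo_fisher",
    "build_design",
    "fit_multinomial",
    "weighted_multinomial",
    "stepwise_aic",
    "fdr_adjust",
    "fcr_adjusted_cis",
    "compare_proportions",
]


# ---------------------------------------------------------------------------
# Global association tests
# ---------------------------------------------------------------------------


@dataclass
class AssociationTestResult:
    variable: str
    test: str  # kruskal_wallis | chi_square | fisher_exact | skipped
    statistic: float | None
    df: int | None
    p_value: float | None
    note: str = ""


def monte_carlo_fisher(
    table: np.ndarray, n_draws: int = 100_000, seed: int | None = 0
) -> float:
    """Monte Carlo Fisher exact p-value for an r x c contingency table.

    Samples tables with the observed margins from the multivariate
    hypergeometric null and counts those no more probable than the observed
    table, with the usual (1 + hits) / (1 + draws) estimator. For 2x2 tables
    the exact two-sided Fisher test is used instead.
    """
    table = np.asarray(table)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    obs_logp = dist.logpmf(table)
    draws = dist.rvs(n_draws, random_state=np.random.default_rng(seed))
    hits = int((dist.logpmf(draws) <= obs_logp + 1e-9).sum())
    return (1 + hits) / (1 + n_draws)


def _categorical_test(name: str, series: pd.Series, classes: pd.Series, n_draws, seed):
    table = pd.crosstab(series, classes)
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return AssociationTestResult(name, "skipped", None, None, None,
                                     "degenerate table (a margin is constant)")
    arr = table.to_numpy()
    expected = stats.contingency.expected_freq(arr)
    if (expected < 5).any():
        p = monte_carlo_fisher(arr, n_draws=n_draws, seed=seed)
        return AssociationTestResult(
            name, "fisher_exact", None, None, float(p),
            f"low expected counts; Monte Carlo with {n_draws} draws, seed {seed}",
        )
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return AssociationTestResult(name, "chi_square", float(chi2), int(df), float(p))


def global_association_tests(
    assignments: pd.Series,
    profiles: pd.DataFrame,
    variables: list[str] | None = None,
    fisher_draws: int = 100_000,
    seed: int = 0,
) -> list[AssociationTestResult]:
    """Screen baseline variables for association with class membership.

    Continuous variables use Kruskal–Wallis across classes; categorical and
    boolean ones use Pearson chi-square without continuity correction,
    falling back to (Monte Carlo) Fisher when any expected count is below 5.
    Constant variables are skipped with a reason.
    """
    if assignments.nunique() < 2:
        raise ValueError("need at least two non-empty classes")
    if variables is None:
        variables = [c for c in profiles.columns if c != "baseline_date"]
    classes = assignments.reindex(profiles.index)
    results = []
    for name in variables:
        col = profiles[name]
        valid = col.notna() & classes.notna()
        col, cls = col[valid], classes[valid]
        if col.nunique() < 2:
            results.append(
                AssociationTestResult(name, "skipped", None, None, None,
                                      "constant variable")
            )
            continue
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            groups = [g.to_numpy(dtype=float) for _, g in col.groupby(cls)]
            stat, p = stats.kruskal(*groups)
            results.append(
                AssociationTestResult(
                    name, "kruskal_wallis", float(stat), len(groups) - 1, float(p)
                )
            )
        else:
            results.append(_categorical_test(name, col, cls, fisher_draws, seed))
    return results


def association_frame(results: list[AssociationTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

#: default reference levels for categorical encodings: HoNOS severity 'None',
#: female gender, Asian ethnicity, earliest education band
DEFAULT_REFERENCES = {
    "gender": "Female",
    "ethnicity": "Asian",
    "education_band": "7-14",
}
HONOS_REFERENCE = "None"


def build_design(
    profiles: pd.DataFrame,
    variables: list[str],
    references: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Numeric design matrix (no intercept) and variable -> columns blocks.

    Continuous and boolean variables map to single columns; categorical
    variables expand to one indicator per non-reference level.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    cols: dict[str, np.ndarray] = {}
    blocks: dict[str, list[str]] = {}
    for name in variables:
        col = profiles[name]
        if pd.api.types.is_bool_dtype(col):
            cols[name] = col.astype(float).to_numpy()
            blocks[name] = [name]
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
            blocks[name] = [name]
        else:
            ref = refs.get(name, HONOS_REFERENCE if name.startswith("honos_") else None)
            levels = [l for l in pd.unique(col.dropna()) if l != ref]
            levels = sorted(map(str, levels))
            blocks[name] = []
            for lev in levels:
                cname = f"{name}[{lev}]"
                cols[cname] = (col.astype(str) == lev).astype(float).to_numpy()
                blocks[name].append(cname)
    X = pd.DataFrame(cols, index=profiles.index)
    return X, blocks


# ---------------------------------------------------------------------------
# Multinomial logistic regression (Newton, weighted)
# ---------------------------------------------------------------------------


@dataclass
class MultinomialModel:
    """Multinomial logit of class membership relative to a reference class.

    Coefficient tables are (non-reference class) x (covariate) DataFrames;
    ``rrr`` = exp(coef) is the relative risk ratio of membership in that
    class versus the reference per unit of the covariate.
    """

    reference_class: int
    class_labels: list  # non-reference classes, fit order
    covariates: list
    coef: pd.DataFrame
    se: pd.DataFrame
    rrr: pd.DataFrame
    p_raw: pd.DataFrame
    p_fdr: pd.DataFrame | None
    ci_low: pd.DataFrame | None
    ci_high: pd.DataFrame | None
    loglik: float
    aic: float
    n_params: int
    converged: bool
    grad_norm: float
    condition_number: float
    separation_flags: pd.DataFrame | None = None
    fcr_level: float | None = None
    n_selected: int | None = None
    n_comparisons: int | None = None


def _mnlogit_newton(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    weights: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """Maximise the (weighted) multinomial log-likelihood by Newton steps.

    Class 0 is the reference with linear predictor fixed at 0; B is
    (p, K-1). Returns (B, loglik, grad_norm, cov, converged).
    """
    n, p = X.shape
    B = np.zeros((p, K - 1))

    def loglik_probs(Bm):
        eta = np.hstack([np.zeros((n, 1)), X @ Bm])
        norm = logsumexp(eta, axis=1)
        ll = float((weights * (eta[np.arange(n), y] - norm)).sum())
        P = np.exp(eta - norm[:, None])
        return ll, P

    ll, P = loglik_probs(B)
    converged = False
    for _ in range(max_iter):
        Yind = np.zeros((n, K - 1))
        nz = y > 0
        Yind[np.flatnonzero(nz), y[nz] - 1] = 1.0
        resid = weights[:, None] * (Yind - P[:, 1:])
        grad = (X.T @ resid).ravel(order="F")  # class-major blocks
        gnorm = float(np.abs(grad).max())
        if gnorm < 1e-6:
            converged = True
            break
        # observed information, (K-1)p x (K-1)p in class-major blocks
        H = np.zeros((p * (K - 1), p * (K - 1)))
        for j in range(K - 1):
            for l in range(j, K - 1):
                pj, pl = P[:, j + 1], P[:, l + 1]
                w = weights * (pj * (1.0 - pj) if j == l else -pj * pl)
                blk = X.T @ (X * w[:, None])
                H[j * p:(j + 1) * p, l * p:(l + 1) * p] = blk
                if l != j:
                    H[l * p:(l + 1) * p, j * p:(j + 1) * p] = blk
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(H.shape[0]), grad)
        # backtracking line search on the log-likelihood
        scale = 1.0
        for _ in range(30):
            Bn = B + scale * step.reshape((K - 1, p)).T
            ll_new, P_new = loglik_probs(Bn)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        B, ll, P = Bn, ll_new, P_new
        if abs(ll_new - ll) < tol * (1 + abs(ll)) and gnorm < 1e-4:
            pass  # keep iterating until the gradient criterion is met

    # final information matrix for standard errors
    H = np.zeros((p * (K - 1), p * (K - 1)))
    for j in range(K - 1):
        for l in range(j, K - 1):
            pj, pl = P[:, j + 1], P[:, l + 1]
            w = weights * (pj * (1.0 - pj) if j == l else -pj * pl)
            blk = X.T @ (X * w[:, None])
            H[j * p:(j + 1) * p, l * p:(l + 1) * p] = blk
            if l != j:
                H[l * p:(l + 1) * p, j * p:(j + 1) * p] = blk
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    Yind = np.zeros((n, K - 1))
    nz = y > 0
    Yind[np.flatnonzero(nz), y[nz] - 1] = 1.0
    grad = (X.T @ (weights[:, None] * (Yind - P[:, 1:]))).ravel(order="F")
    return B, ll, float(np.abs(grad).max()), cov, converged


def fit_multinomial(
    assignments: pd.Series,
    design: pd.DataFrame,
    reference_class,
    weights: pd.Series | np.ndarray | None = None,
    alpha: float = 0.05,
    adjust: bool = True,
) -> MultinomialModel:
    """ML multinomial logit of class on covariates, reference-class coded.

    ``design`` holds the covariate columns (an intercept is added
    internally). Wald p-values come from the inverse observed information;
    when ``adjust`` is set, Benjamini–Hochberg-adjusted p-values over all
    non-intercept coefficients and FCR-adjusted confidence intervals at the
    implied level are attached.
    """
    common = design.index.intersection(assignments.index)
    design = design.loc[common]
    y_raw = assignments.loc[common]
    if weights is not None:
        weights = np.asarray(pd.Series(weights).loc[common], dtype=float) \
            if isinstance(weights, pd.Series) else np.asarray(weights, dtype=float)
    else:
        weights = np.ones(len(common))

    classes = sorted(y_raw.unique())
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class} not present")
    others = [c for c in classes if c != reference_class]
    class_index = {reference_class: 0, **{c: i + 1 for i, c in enumerate(others)}}
    y = y_raw.map(class_index).to_numpy()

    Xdf = design.astype(float)
    X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy()])
    covs = ["intercept", *Xdf.columns]
    # rank / collinearity check
    Xs = X[:, 1:]
    if Xs.shape[1]:
        sd = Xs.std(axis=0)
        if (sd == 0).any():
            aliased = [c for c, s in zip(Xdf.columns, sd) if s == 0]
            raise ValueError(f"rank-deficient design: constant columns {aliased}")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("rank-deficient design after encoding")
        cond = float(np.linalg.cond((Xs - Xs.mean(0)) / sd))
    else:
        cond = 1.0

    K = len(classes)
    B, ll, gnorm, cov, converged = _mnlogit_newton(X, y, K, weights)
    p = X.shape[1]
    se = np.sqrt(np.diag(cov)).reshape((K - 1, p))
    coef = B.T  # (K-1, p)
    z = coef / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    sep = np.abs(coef) > 15  # diverging coefficients indicate separation
    if sep.any():
        logger.warning("possible separation: %d coefficient(s) diverging", sep.sum())

    idx = pd.Index(others, name="class_vs_ref")
    cols = pd.Index(covs, name="covariate")
    as_df = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    n_params = p * (K - 1)
    model = MultinomialModel(
        reference_class=reference_class,
        class_labels=others,
        covariates=covs,
        coef=as_df(coef),
        se=as_df(se),
        rrr=as_df(np.exp(coef)),
        p_raw=as_df(p_raw),
        p_fdr=None,
        ci_low=None,
        ci_high=None,
        loglik=ll,
        aic=-2 * ll + 2 * n_params,
        n_params=n_params,
        converged=converged,
        grad_norm=gnorm,
        condition_number=cond,
        separation_flags=as_df(sep),
    )
    if adjust:
        attach_adjustments(model, alpha=alpha)
    return model


def weighted_multinomial(
    posteriors: pd.DataFrame,
    design: pd.DataFrame,
    reference_class,
    alpha: float = 0.05,
    adjust: bool = True,
) -> MultinomialModel:
    """Posterior-weighted sensitivity fit.

    Each subject contributes one pseudo-observation per class, weighted by
    its posterior membership probability (expanded-data multinomial
    likelihood); one-hot posteriors reduce exactly to the hard-assignment
    fit.
    """
    P = posteriors.reindex(design.index)
    rows_sums = P.sum(axis=1)
    if not np.allclose(rows_sums.to_numpy(), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    long_idx, long_y, long_w = [], [], []
    for cls in P.columns:
        w = P[cls].to_numpy()
        keep = w > 1e-12
        long_idx.append(np.flatnonzero(keep))
        long_y.append(np.full(int(keep.sum()), cls))
        long_w.append(w[keep])
    pos = np.concatenate(long_idx)
    Xrep = design.iloc[pos].reset_index(drop=True)
    yrep = pd.Series(np.concatenate(long_y), index=Xrep.index)
    wrep = np.concatenate(long_w)
    return fit_multinomial(
        yrep, Xrep, reference_class, weights=wrep, alpha=alpha, adjust=adjust
    )


# ---------------------------------------------------------------------------
# Multiplicity adjustments
# ---------------------------------------------------------------------------


def fdr_adjust(p_matrix) -> np.ndarray:
    """Benjamini–Hochberg step-up over the pooled p-values (NaN passthrough)."""
    p = np.asarray(p_matrix, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    out = np.full(flat.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    return out.reshape(p.shape)


def fcr_adjusted_cis(
    coef, se, n_selected: int, n_total: int, alpha: float = 0.05
):
    """False-coverage-rate adjusted Wald intervals on the RRR scale.

    With R of m coefficients selected (by BH at level alpha), intervals for
    the selected set are two-sided at level 1 - R * alpha / m, i.e. use the
    Normal quantile at 1 - R * alpha / (2 m). R = m recovers ordinary 95%
    intervals; R = 0 means nothing is selected and no intervals apply.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    if n_selected == 0:
        nan = np.full(coef.shape, np.nan)
        return nan, nan.copy()
    zq = stats.norm.ppf(1 - n_selected * alpha / (2 * n_total))
    return np.exp(coef - zq * se), np.exp(coef + zq * se)


def attach_adjustments(model: MultinomialModel, alpha: float = 0.05) -> None:
    """Fill BH-adjusted p-values and FCR-adjusted CIs on a fitted model.

    The comparison family m is every class-contrast x covariate coefficient
    in the model excluding the intercepts; R is the number of BH-discoveries
    at ``alpha``.
    """
    non_int = [c for c in model.covariates if c != "intercept"]
    p = model.p_raw[non_int].to_numpy()
    m = int(np.isfinite(p).sum())
    p_adj = fdr_adjust(p)
    R = int((p_adj <= alpha).sum()) if m else 0
    p_fdr = model.p_raw.copy()
    p_fdr.loc[:, non_int] = p_adj
    model.p_fdr = p_fdr
    model.n_comparisons = m
    model.n_selected = R
    lo = model.coef.copy()
    hi = model.coef.copy()
    if R > 0:
        l, h = fcr_adjusted_cis(
            model.coef[non_int].to_numpy(),
            model.se[non_int].to_numpy(),
            R,
            m,
            alpha=alpha,
        )
        model.fcr_level = 1 - R * alpha / m
    else:
        l = np.full(p.shape, np.nan)
        h = np.full(p.shape, np.nan)
        model.fcr_level = None
    # intercept columns keep unadjusted 95% intervals
    zq = stats.norm.ppf(0.975)
    lo.loc[:, :] = np.exp(model.coef.to_numpy() - zq * model.se.to_numpy())
    hi.loc[:, :] = np.exp(model.coef.to_numpy() + zq * model.se.to_numpy())
    lo.loc[:, non_int] = l
    hi.loc[:, non_int] = h
    model.ci_low = lo
    model.ci_high = hi
    logger.info("FDR/FCR family: m=%d comparisons, R=%d selected", m, R)


# ---------------------------------------------------------------------------
# Stepwise selection over variable blocks
# ---------------------------------------------------------------------------


def stepwise_aic(
    assignments: pd.Series,
    design: pd.DataFrame,
    blocks: dict[str, list[str]],
    candidate_blocks: list[str],
    forced_blocks: list[str],
    reference_class,
    alpha: float = 0.05,
) -> tuple[MultinomialModel, pd.DataFrame]:
    """Backward elimination of whole variable blocks by AIC.

    Starts from the full model (forced adjusters plus all candidates) and
    repeatedly removes the candidate block whose deletion lowers AIC most,
    stopping when no deletion lowers AIC. Forced blocks are never removed.
    Returns the selected model (with multiplicity adjustments) and a
    per-step ledger of attempted deletions and their AICs.
    """
    current = list(candidate_blocks)

    def cols_for(block_names):
        out = []
        for b in forced_blocks + block_names:
            out.extend(blocks[b])
        return out

    def fit_cols(block_names):
        return fit_multinomial(
            assignments, design[cols_for(block_names)], reference_class, adjust=False
        )

    base = fit_cols(current)
    ledger_rows = [
        {"step": 0, "action": "full model", "variable": None, "aic": base.aic}
    ]
    step = 0
    while current:
        step += 1
        trials = []
        for b in current:
            reduced = [x for x in current if x != b]
            trial = fit_cols(reduced)
            trials.append((trial.aic, b, trial))
            ledger_rows.append(
                {"step": step, "action": "try drop", "variable": b, "aic": trial.aic}
            )
        best_aic, best_block, best_model = min(trials, key=lambda t: t[0])
        if best_aic < base.aic:
            current = [x for x in current if x != best_block]
            base = best_model
            ledger_rows.append(
                {"step": step, "action": "drop", "variable": best_block, "aic": best_aic}
            )
        else:
            break
    final = fit_multinomial(
        assignments, design[cols_for(current)], reference_class, alpha=alpha, adjust=True
    )
    final.selected_blocks = forced_blocks + current  # type: ignore[attr-defined]
    return final, pd.DataFrame(ledger_rows)


# ---------------------------------------------------------------------------
# Diagnosis proportions across trajectories
# ---------------------------------------------------------------------------


def compare_proportions(
    assignments: pd.Series,
    diagnoses: pd.DataFrame,
    focus_pair: tuple = (3, 4),
    fisher_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tests of diagnosis prevalence across classes and for one class pair.

    Diagnosis flags are any-time-during-follow-up indicators. For each
    diagnosis the all-classes 2 x K table and the ``focus_pair`` 2 x 2 table
    are tested (chi-square, or Fisher under low expected counts); degenerate
    tables are skipped with a reason.
    """
    rows = []
    for diag, g in diagnoses.groupby("diagnosis"):
        flag = assignments.index.isin(g["subject_id"].unique())
        flag = pd.Series(flag, index=assignments.index)
        for scope, mask in [
            ("all_classes", pd.Series(True, index=assignments.index)),
            (
                f"class_{focus_pair[0]}_vs_{focus_pair[1]}",
                assignments.isin(focus_pair),
            ),
        ]:
            sub_flag, sub_cls = flag[mask], assignments[mask]
            tab = pd.crosstab(sub_flag, sub_cls)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append(
                    {
                        "diagnosis": diag,
                        "scope": scope,
                        "test": "skipped",
                        "statistic": None,
                        "df": None,
                        "p_value": None,
                        "note": "degenerate table",
                    }
                )
                continue
            res = _categorical_test(diag, sub_flag, sub_cls, fisher_draws, seed)
            rows.append(
                {
                    "diagnosis": diag,
                    "scope": scope,
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "note": res.note,
                }
            )
    return pd.DataFrame(rows)
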