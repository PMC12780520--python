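"""Covariate association models for the CFM outcome types.

The inferential chain mirrors standard practice in the child-nutrition
literature: Pearson chi-square screening of each categorical covariate
against the outcome (covariates pass at p <= 0.05), multinomial logistic
regression of the CFM type against the screened covariates -- with
underweight children as the reference outcome for the undernutrition
overlaps (CUW, CUS, CUWS) and stunted children as the reference for CSO
(that model is binary) -- backward elimination of whole covariate blocks
by likelihood-ratio test until only significant blocks remain, and
variance-inflation-factor collinearity diagnostics on the dummy-coded
design matrix.

The multinomial likelihood is maximised by Newton-Raphson on the stacked
score with step-halving, convergence at max |score| < 1e-8 or relative
log-likelihood change < 1e-10, capped at 100 iterations.  Complete
separation (any |coefficient| > 15 during iteration) triggers a mild ridge
(1e-6) refit with a warning flag.  Wald 95% CIs: exp(beta +/- 1.96 se).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "FittedAssociationModel",
    "ORResult",
    "build_design_matrix",
    "chisq_screen",
    "fit_multinomial",
    "lr_test_block",
    "backward_eliminate",
    "vif",
    "or_table",
]

logger = logging.getLogger(__name__)

MAX_ITER = 100
SCORE_TOL = 1e-8
LL_RELTOL = 1e-10
SEPARATION_CUT = 15.0
RIDGE_FALLBACK = 1e-6
Z975 = 1.959963984540054


@dataclass
class DesignMatrix:
    """Intercept + dummy-coded covariate columns with block bookkeeping."""

    X: np.ndarray
    columns: List[str]
    covariate_blocks: Dict[str, List[int]]
    reference_levels: Dict[str, str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def drop_block(self, covariate: str) -> "DesignMatrix":
        keep = [j for j in range(self.p) if j not in set(self.covariate_blocks[covariate])]
        remap = {old: new for new, old in enumerate(keep)}
        blocks = {
            c: [remap[j] for j in cols]
            for c, cols in self.covariate_blocks.items()
            if c != covariate
        }
        return DesignMatrix(
            X=self.X[:, keep],
            columns=[self.columns[j] for j in keep],
            covariate_blocks=blocks,
            reference_levels={c: r for c, r in self.reference_levels.items() if c != covariate},
        )


def build_design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Optional[Mapping[str, str]] = None,
) -> DesignMatrix:
    """Dummy-code categorical covariates with one declared reference level each.

    The reference level defaults to the first level in sorted order.
    Aliased (all-zero or duplicate) columns are dropped; the result must be
    full column rank.
    """
    reference_levels = dict(reference_levels or {})
    n = len(df)
    cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["intercept"]
    blocks: Dict[str, List[int]] = {}
    refs: Dict[str, str] = {}

    for cov in covariates:
        values = df[cov].astype(str)
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level")
        ref = str(reference_levels.get(cov, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of {cov!r}")
        refs[cov] = ref
        blocks[cov] = []
        for lev in levels:
            if lev == ref:
                continue
            col = (values == lev).to_numpy(dtype=float)
            blocks[cov].append(len(names))
            names.append(f"{cov}[{lev}]")
            cols.append(col)

    X = np.column_stack(cols)
    # drop aliased columns (exact collinearity) so the Hessian is invertible
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep: List[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.warning("dropping aliased design columns: %s", dropped)
        remap = {old: new for new, old in enumerate(keep)}
        blocks = {c: [remap[j] for j in js if j in remap] for c, js in blocks.items()}
        blocks = {c: js for c, js in blocks.items() if js}
        names = [names[j] for j in keep]
        X = X[:, keep]

    return DesignMatrix(X=X, columns=names, covariate_blocks=blocks, reference_levels=refs)


def chisq_screen(
    df: pd.DataFrame, covariate: str, outcome: str
) -> Tuple[float, int, float]:
    """Pearson chi-square of covariate x outcome on complete pairs.

    Returns (statistic, df, p).  A covariate passes the screen at
    p <= 0.05.  Degenerate single-row/column tables raise.
    """
    sub = df[[covariate, outcome]].dropna()
    table = pd.crosstab(sub[covariate], sub[outcome])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table for {covariate!r} x {outcome!r}: shape {table.shape}"
        )
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class FittedAssociationModel:
    outcome_levels: List[str]          # reference outcome first
    ref_outcome: str
    design: DesignMatrix
    coefficients: np.ndarray           # (K-1, p) log-odds vs reference outcome
    covariance: np.ndarray             # ((K-1)p, (K-1)p)
    loglik: float
    converged: bool
    n_iterations: int
    n_obs: int
    separation_flag: bool = False
    ridge: float = 0.0
    retained_covariates: List[str] = field(default_factory=list)
    eliminated: List[Tuple[str, float]] = field(default_factory=list)

    def standard_errors(self) -> np.ndarray:
        se = np.sqrt(np.maximum(np.diag(self.covariance), 0.0))
        return se.reshape(self.coefficients.shape)

    def coef_frame(self) -> pd.DataFrame:
        se = self.standard_errors()
        rows = []
        for k, level in enumerate(self.outcome_levels[1:]):
            for j, col in enumerate(self.design.columns):
                b = self.coefficients[k, j]
                rows.append(
                    {
                        "outcome": level,
                        "column": col,
                        "coef": b,
                        "se": se[k, j],
                        "or": np.exp(b),
                        "ci_low": np.exp(b - Z975 * se[k, j]),
                        "ci_high": np.exp(b + Z975 * se[k, j]),
                    }
                )
        return pd.DataFrame(rows)


def _encode_outcome(y: Sequence, ref_outcome: str) -> Tuple[np.ndarray, List[str]]:
    y_arr = pd.Series(y).astype(str)
    levels = sorted(y_arr.unique())
    if str(ref_outcome) not in levels:
        raise ValueError(f"reference outcome {ref_outcome!r} not among levels {levels}")
    ordered = [str(ref_outcome)] + [l for l in levels if l != str(ref_outcome)]
    codes = y_arr.map({l: i for i, l in enumerate(ordered)}).to_numpy()
    return codes, ordered


def _multinomial_ll(beta: np.ndarray, X: np.ndarray, Y: np.ndarray, w: np.ndarray, ridge: float):
    """Log-likelihood, score and probabilities for stacked beta ((K-1) x p)."""
    eta = X @ beta.T                                  # n x (K-1)
    eta = np.column_stack([np.zeros(len(X)), eta])    # reference column 0
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    P = expeta / expeta.sum(axis=1, keepdims=True)    # n x K
    ll = float((w * (np.take_along_axis(eta, Y[:, None], axis=1).ravel()
                     - np.log(expeta.sum(axis=1)))).sum())
    ll -= 0.5 * ridge * float((beta ** 2).sum())
    K = P.shape[1]
    score = np.empty_like(beta)
    for k in range(1, K):
        resid = w * ((Y == k).astype(float) - P[:, k])
        score[k - 1] = X.T @ resid
    score -= ridge * beta
    return ll, score, P


def _multinomial_hessian(X: np.ndarray, P: np.ndarray, w: np.ndarray, ridge: float) -> np.ndarray:
    """Negative Hessian (observed information) of the multinomial log-likelihood."""
    K = P.shape[1]
    p = X.shape[1]
    H = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(1, K):
        for j in range(1, K):
            wkj = w * P[:, k] * ((1.0 if k == j else 0.0) - P[:, j])
            H[(k - 1) * p:k * p, (j - 1) * p:j * p] = X.T @ (X * wkj[:, None])
    H += ridge * np.eye((K - 1) * p)
    return H


def fit_multinomial(
    design: DesignMatrix,
    y: Sequence,
    ref_outcome: str,
    weights: Optional[Sequence[float]] = None,
    ridge: float = 0.0,
) -> FittedAssociationModel:
    """Maximum-likelihood multinomial logit with ``ref_outcome`` as baseline.

    A two-level outcome reduces exactly to binary logistic regression.
    Non-convergence is reported, not raised; detected separation triggers a
    ridge (1e-6) refit flagged on the result.
    """
    X = design.X
    Y, levels = _encode_outcome(y, ref_outcome)
    if len(Y) != len(X):
        raise ValueError("outcome length does not match design matrix")
    counts = np.bincount(Y, minlength=len(levels))
    if np.any(counts == 0):
        raise ValueError("every outcome level needs at least one observation")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)

    K = len(levels)
    p = X.shape[1]
    beta = np.zeros((K - 1, p))
    ll, score, P = _multinomial_ll(beta, X, Y, w, ridge)

    converged = False
    separation = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        H = _multinomial_hessian(X, P, w, ridge)
        try:
            step = np.linalg.solve(H, score.ravel()).reshape(beta.shape)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score.ravel(), rcond=None)[0].reshape(beta.shape)
        # step-halving: the log-likelihood must not decrease
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            ll_new, score_new, P_new = _multinomial_ll(trial, X, Y, w, ridge)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll_prev, ll, score, P = trial, ll, ll_new, score_new, P_new
        if np.abs(beta).max() > SEPARATION_CUT:
            separation = True
            break
        if np.abs(score).max() < SCORE_TOL or abs(ll - ll_prev) < LL_RELTOL * (abs(ll_prev) + 1e-12):
            converged = True
            break

    if separation and ridge == 0.0:
        logger.warning("complete separation detected; refitting with ridge %g", RIDGE_FALLBACK)
        refit = fit_multinomial(design, y, ref_outcome, weights=weights, ridge=RIDGE_FALLBACK)
        refit.separation_flag = True
        return refit

    H = _multinomial_hessian(X, P, w, ridge)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)

    return FittedAssociationModel(
        outcome_levels=levels,
        ref_outcome=str(ref_outcome),
        design=design,
        coefficients=beta,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_iterations=it,
        n_obs=len(X),
        separation_flag=separation,
        ridge=ridge,
        retained_covariates=list(design.covariate_blocks),
    )


def lr_test_block(
    full: FittedAssociationModel,
    y: Sequence,
    covariate: str,
    weights: Optional[Sequence[float]] = None,
) -> Tuple[float, int, float]:
    """Likelihood-ratio test of one covariate block (all dummies, all equations)."""
    reduced_design = full.design.drop_block(covariate)
    reduced = fit_multinomial(reduced_design, y, full.ref_outcome, weights=weights)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    dof = (len(full.outcome_levels) - 1) * len(full.design.covariate_blocks[covariate])
    pval = float(stats.chi2.sf(stat, dof))
    return stat, dof, pval


def backward_eliminate(
    df: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    ref_outcome: str,
    alpha: float = 0.05,
    reference_levels: Optional[Mapping[str, str]] = None,
    weights: Optional[str] = None,
) -> FittedAssociationModel:
    """Backward elimination of covariate blocks by likelihood-ratio test.

    Repeatedly removes the block with the largest LR p-value above
    ``alpha`` (whole covariate at a time, jointly across outcome
    equations) and refits, until every remaining block is significant.
    Complete-case analysis within the model; the elimination order and
    p-values are recorded on the returned fit.
    """
    cols = list(covariates) + [outcome] + ([weights] if weights else [])
    data = df[cols].dropna()
    n_dropped = len(df) - len(data)
    if n_dropped:
        logger.info("complete-case analysis drops %d of %d records", n_dropped, len(df))
    w = data[weights].to_numpy(dtype=float) if weights else None

    current = list(covariates)
    eliminated: List[Tuple[str, float]] = []
    while True:
        if not current:
            logger.warning("all covariates eliminated; returning intercept-only model")
            design = build_design_matrix(data, [], reference_levels)
            model = fit_multinomial(design, data[outcome], ref_outcome, weights=w)
            model.eliminated = eliminated
            model.retained_covariates = []
            return model
        design = build_design_matrix(data, current, reference_levels)
        model = fit_multinomial(design, data[outcome], ref_outcome, weights=w)
        pvals = {
            cov: lr_test_block(model, data[outcome], cov, weights=w)[2] for cov in current
        }
        worst, worst_p = max(pvals.items(), key=lambda kv: kv[1])
        if worst_p <= alpha:
            model.eliminated = eliminated
            model.retained_covariates = current
            return model
        eliminated.append((worst, worst_p))
        current = [c for c in current if c != worst]


def vif(design: DesignMatrix) -> Dict[str, float]:
    """Variance inflation factor per non-intercept column.

    VIF_j = 1 / (1 - R^2_j), R^2_j from OLS of column j on the other
    non-intercept columns plus intercept.  Exact collinearity yields
    ``inf`` (flagged sentinel) rather than an exception.
    """
    non_int = [j for j, c in enumerate(design.columns) if c != "intercept"]
    if len(non_int) < 2:
        raise ValueError("VIF needs at least two non-intercept columns")
    if design.n <= design.p:
        raise ValueError("VIF needs more observations than columns")
    out: Dict[str, float] = {}
    for j in non_int:
        others = [k for k in non_int if k != j]
        Z = np.column_stack([np.ones(design.n), design.X[:, others]])
        yj = design.X[:, j]
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[design.columns[j]] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[design.columns[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class ORResult:
    outcome: str
    covariate: str
    level: str
    or_value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    adjusted: bool
    significant: bool
    is_reference: bool


def or_table(
    models: Mapping[str, FittedAssociationModel], adjusted: bool = True
) -> pd.DataFrame:
    """Tidy OR table over fitted models, one row per (outcome, covariate level).

    ``models`` maps a model tag to a fit; every non-reference outcome level
    of each fit is reported.  Reference levels appear as OR 1.00 with no
    CI; a row is starred when its 95% CI excludes 1.
    """
    rows: List[ORResult] = []
    for tag, model in models.items():
        if not model.converged and not model.separation_flag:
            logger.warning("model %s did not converge; reporting anyway", tag)
        se = model.standard_errors()
        for k, outcome in enumerate(model.outcome_levels[1:]):
            for cov, block in model.design.covariate_blocks.items():
                ref = model.design.reference_levels[cov]
                rows.append(
                    ORResult(outcome, cov, ref, 1.0, None, None, adjusted, False, True)
                )
                for j in block:
                    level = model.design.columns[j].split("[", 1)[1].rstrip("]")
                    b, s = model.coefficients[k, j], se[k, j]
                    lo, hi = np.exp(b - Z975 * s), np.exp(b + Z975 * s)
                    rows.append(
                        ORResult(
                            outcome, cov, level, float(np.exp(b)), float(lo), float(hi),
                            adjusted, bool(lo > 1.0 or hi < 1.0), False,
                        )
                    )
    columns = ["outcome", "covariate", "level", "or_value", "ci_low", "ci_high",
               "adjusted", "significant", "is_reference"]
    return pd.DataFrame([vars(r) for r in rows], columns=columns)
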