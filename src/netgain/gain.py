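"""Genetic association interaction network (GAIN) inference.

Two routes build the N×N weighted matrix whose off-diagonals measure the
pairwise interaction effect of gene expression on the phenotype and whose
diagonal measures per-gene main effects:

* **dcGAIN** — the Fisher z-test for a between-group difference in pairwise
  Pearson correlation. For groups of sizes m1 and m0 the off-diagonal is

      Z_ij = |z(r_ij^1) - z(r_ij^0)| / sqrt(1/(m1-3) + 1/(m0-3))

  with z the Fisher transform, and the diagonal is a Welch two-sample
  t-statistic per gene. Off-diagonals are non-negative by construction.

* **reGAIN** — a generalized linear model with a full multiplicative
  interaction per unordered gene pair,

      g(E[D]) = b0 + b_i G_i + b_j G_j + b_ij G_i G_j (+ covariates)

  where g is the logit link for case/control outcomes or identity for
  quantitative traits. The off-diagonal is the standardized interaction
  coefficient (Wald z by default), the diagonal the standardized
  coefficient from a single-gene model. Off-diagonals carry sign.

All pair fits run through a vectorized batched IRLS solver so a full
matrix (and the many matrices a permutation null requires) stays cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GainMatrix",
    "groupwise_correlation",
    "fisher_z",
    "dcgain",
    "regain",
]

#: correlations are clamped to +/-(1 - _R_CLAMP) before the Fisher transform
_R_CLAMP = 1e-7


@dataclass
class GainMatrix:
    """Symmetric weighted gene-gene interaction matrix.

    ``weights`` holds interaction scores off the diagonal and main-effect
    scores on the diagonal. ``signed`` records whether off-diagonals carry
    sign (reGAIN) or are non-negative magnitudes (dcGAIN).
    """

    weights: np.ndarray
    gene_ids: list[str]
    method: str
    signed: bool
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-8, equal_nan=True):
            raise ValueError("weights must be symmetric")
        if len(self.gene_ids) != w.shape[0]:
            raise ValueError("gene id count must match matrix size")
        self.weights = w

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    def off_diagonal(self) -> np.ndarray:
        out = self.weights.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.gene_ids, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# dcGAIN
# ---------------------------------------------------------------------------

def groupwise_correlation(data: ExpressionDataset, group: int) -> np.ndarray:
    """Pearson correlation between all gene pairs within one phenotype group.

    Genes with zero variance inside the group get correlation 0 with every
    other gene (a flat gene carries no co-expression signal); the diagonal
    stays 1.
    """
    idx = data.group_indices(group)
    if idx.size < 4:
        raise ValueError(
            f"group {group} has {idx.size} samples; need at least 4 "
            "(the Fisher z denominator requires m - 3 > 0)"
        )
    sub = data.matrix[:, idx]
    sd = sub.std(axis=1)
    flat = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(sub)
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s) in group %d; their correlations set to 0",
            int(flat.sum()), group,
        )
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r, absolute: bool = False):
    """Fisher transform of a correlation, z = (1/2) ln((1+r)/(1-r)) = atanh(r).

    ``absolute=True`` transforms the correlation magnitude, z = atanh(|r|),
    discarding the sign of r. (Wrapping the log *argument* in absolute
    value instead would change nothing: (1+r)/(1-r) is positive on the
    whole valid domain.) The difference between the two variants matters
    downstream only when a pair's correlation changes sign between groups.
    Inputs with |r| = 1 are clamped so the result stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation magnitude exceeds 1")
    rc = np.clip(r, -1 + _R_CLAMP, 1 - _R_CLAMP)
    out = np.arctanh(np.abs(rc)) if absolute else np.arctanh(rc)
    return out if out.ndim else float(out)


def dcgain(data: ExpressionDataset, absolute_z: bool = False) -> GainMatrix:
    """Differential co-expression GAIN via the Fisher z-test.

    Off-diagonals are the non-negative z-test statistic for the
    between-group correlation difference; the diagonal holds per-gene
    Welch t-statistics (cases minus controls). Requires a binary phenotype
    with more than 3 samples per group.
    """
    data.require_binary()
    m1 = data.group_indices(1).size
    m0 = data.group_indices(0).size
    if min(m0, m1) <= 3:
        raise ValueError(
            f"group sizes ({m1} cases, {m0} controls) too small: the Fisher "
            "z-test denominator sqrt(1/(m1-3) + 1/(m0-3)) needs > 3 per group"
        )
    z1 = fisher_z(groupwise_correlation(data, 1), absolute=absolute_z)
    z0 = fisher_z(groupwise_correlation(data, 0), absolute=absolute_z)
    denom = np.sqrt(1.0 / (m1 - 3) + 1.0 / (m0 - 3))
    w = np.abs(z1 - z0) / denom
    cases = data.matrix[:, data.group_indices(1)]
    controls = data.matrix[:, data.group_indices(0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(cases, controls, axis=1, equal_var=False).statistic
    t = np.where(np.isfinite(t), t, 0.0)
    np.fill_diagonal(w, t)
    return GainMatrix(
        weights=w,
        gene_ids=list(data.gene_ids),
        method="dcgain",
        signed=False,
        info={"m1": m1, "m0": m0, "absolute_z": absolute_z},
    )


# ---------------------------------------------------------------------------
# reGAIN: batched GLM machinery
# ---------------------------------------------------------------------------

def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -30.0, 30.0)))


def _batched_logistic_irls(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 30,
):
    """Fit P logistic regressions at once by batched Newton/IRLS.

    ``x`` has shape (P, M, K) and ``y`` shape (M,). An optional L2 penalty
    ``ridge`` (never applied to the intercept, assumed in column 0) keeps
    separated fits finite. Returns (beta, se, converged) with shapes
    (P, K), (P, K), (P,).
    """
    p, m, k = x.shape
    beta = np.zeros((p, k))
    pen = np.zeros((k, k))
    if ridge > 0:
        pen = ridge * np.eye(k)
        pen[0, 0] = 0.0
    converged = np.zeros(p, dtype=bool)
    hessian = np.empty((p, k, k))
    active = np.arange(p)
    for _ in range(max_iter):
        xa = x[active]
        ba = beta[active]
        xat = np.transpose(xa, (0, 2, 1))
        eta = (xa @ ba[:, :, None])[:, :, 0]
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = (xat @ (y[None, :] - mu)[:, :, None])[:, :, 0] - ba @ pen
        xtwx = xat @ (xa * w[:, :, None]) + pen[None, :, :]
        try:
            step = np.linalg.solve(xtwx, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(xtwx + 1e-8 * np.eye(k), grad[:, :, None])[:, :, 0]
        beta[active] = ba + step
        hessian[active] = xtwx
        done = np.max(np.abs(step), axis=1) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    cov = np.linalg.inv(hessian)
    se = np.sqrt(np.clip(np.einsum("pkk->pk", cov), 0.0, None))
    # separation shows up as runaway coefficients even when steps shrink
    blown = np.max(np.abs(beta), axis=1) > 1e3
    return beta, se, converged & ~blown


def _batched_firth_logistic(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Firth bias-reduced logistic regression, batched over P designs.

    The Firth penalty (Jeffreys prior) keeps estimates finite under
    complete or quasi-complete separation, where plain maximum likelihood
    diverges; used as the fallback path for pairs the unpenalized IRLS
    cannot fit. Score: U*(b) = X'(y - mu + h(1/2 - mu)) with h the hat
    diagonals of the weighted design.
    """
    p, m, k = x.shape
    beta = np.zeros((p, k))
    xt = np.transpose(x, (0, 2, 1))
    hessian = np.empty((p, k, k))
    step_cap = 5.0  # damped Newton: Firth surface can overshoot early
    for _ in range(max_iter):
        eta = (x @ beta[:, :, None])[:, :, 0]
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = xt @ (x * w[:, :, None])
        cov = np.linalg.inv(xtwx)
        # hat diagonals h_m = w_m * x_m' (X'WX)^-1 x_m
        h = w * np.sum((x @ cov) * x, axis=2)
        resid = y[None, :] - mu + h * (0.5 - mu)
        grad = (xt @ resid[:, :, None])[:, :, 0]
        step = np.linalg.solve(xtwx, grad[:, :, None])[:, :, 0]
        norm = np.max(np.abs(step), axis=1, keepdims=True)
        step = np.where(norm > step_cap, step * (step_cap / norm), step)
        beta = beta + step
        hessian = xtwx
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(hessian)
    se = np.sqrt(np.clip(np.einsum("pkk->pk", cov), 0.0, None))
    return beta, se


def _batched_ols(x: np.ndarray, y: np.ndarray):
    """Fit P ordinary least-squares models at once; Gaussian-family reGAIN."""
    p, m, k = x.shape
    xt = np.transpose(x, (0, 2, 1))
    xtx = xt @ x
    xty = xt @ y
    try:
        beta = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        beta = np.linalg.solve(xtx + 1e-10 * np.eye(k), xty[:, :, None])[:, :, 0]
    resid = y[None, :] - np.einsum("pmk,pk->pm", x, beta)
    dof = max(m - k, 1)
    sigma2 = np.sum(resid**2, axis=1) / dof
    cov = np.linalg.inv(xtx) * sigma2[:, None, None]
    se = np.sqrt(np.clip(np.einsum("pkk->pk", cov), 0.0, None))
    return beta, se, np.ones(p, dtype=bool)


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (m - mu) / sd


def _covariate_columns(data: ExpressionDataset) -> np.ndarray | None:
    if data.covariates is None or data.covariates.shape[1] == 0:
        return None
    cov = pd.get_dummies(data.covariates, drop_first=True).to_numpy(dtype=float)
    mu = cov.mean(axis=0, keepdims=True)
    sd = cov.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (cov - mu) / sd


def regain(
    data: ExpressionDataset,
    family: str = "binomial",
    stat: str = "beta",
) -> GainMatrix:
    """Regression GAIN: per-pair interaction GLMs plus single-gene diagonal.

    Gene predictors are z-scored and the product term is formed from the
    z-scored genes, so coefficients are standardized. ``stat`` selects the
    matrix element: ``"beta"`` (the standardized coefficient, the default)
    or ``"wald"`` (coefficient / standard error). At 20–40 samples the
    Wald form systematically deflates interaction statistics for pairs
    containing a strong main effect, so the coefficient is the safer
    ranking currency for small designs. Covariates attached
    to the dataset enter every model. Pairs whose unpenalized logistic fit
    fails to converge — complete separation is routine at small M and is
    itself a sign of a strong effect — are refit with Firth bias-reduced
    logistic regression and logged; the matrix is always total.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unsupported family {family!r}")
    if stat not in ("wald", "beta"):
        raise ValueError(f"unknown stat {stat!r}")
    if family == "binomial":
        data.require_binary()
    y = np.asarray(data.phenotype, dtype=float)
    g = _standardize_rows(data.matrix)
    n, m = g.shape
    cov = _covariate_columns(data)
    n_cov = 0 if cov is None else cov.shape[1]

    def build_design(columns: list[np.ndarray]) -> np.ndarray:
        # columns: list of (P, M) arrays following the intercept
        p = columns[0].shape[0]
        k = 1 + len(columns) + n_cov
        x = np.empty((p, m, k))
        x[:, :, 0] = 1.0
        for c, col in enumerate(columns, start=1):
            x[:, :, c] = col
        if cov is not None:
            x[:, :, 1 + len(columns):] = cov[None, :, :]
        return x

    def fit(x: np.ndarray):
        if family == "binomial":
            beta, se, ok = _batched_logistic_irls(x, y)
            if not ok.all():
                logger.warning(
                    "%d/%d fits non-convergent or separated; Firth fallback",
                    int((~ok).sum()), x.shape[0],
                )
                bad = ~ok
                beta_f, se_f = _batched_firth_logistic(x[bad], y)
                beta[bad] = beta_f
                se[bad] = se_f
            return beta, se
        beta, se, _ = _batched_ols(x, y)
        return beta, se

    # single-gene diagonal: outcome ~ 1 + G_i (+ covariates)
    beta_d, se_d = fit(build_design([g]))
    diag = beta_d[:, 1] / se_d[:, 1] if stat == "wald" else beta_d[:, 1]

    # pairwise interaction models: outcome ~ 1 + G_i + G_j + G_i*G_j (+cov)
    iu, ju = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    if iu.size:
        gi, gj = g[iu], g[ju]
        beta_p, se_p = fit(build_design([gi, gj, gi * gj]))
        inter = beta_p[:, 3] / se_p[:, 3] if stat == "wald" else beta_p[:, 3]
        w[iu, ju] = inter
        w[ju, iu] = inter
    np.fill_diagonal(w, diag)
    return GainMatrix(
        weights=w,
        gene_ids=list(data.gene_ids),
        method="regain",
        signed=True,
        info={"family": family, "stat": stat, "n_covariates": n_cov},
    )
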