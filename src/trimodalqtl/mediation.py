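"""Linear causal mediation between molecular modalities.

Fits the two linear structural equations

  M_i = a0 + a1 X_i + a2' C_i + e_im
  Y_i = b0 + b1 M_i + b2 X_i + b3' C_i + e_iy

where the treatment X is a genotype principal component, the mediator and
outcome are variance-stabilized molecular traits (accessibility, promoter
contact, expression, depending on the model), and C are observed
confounders (model III optionally includes accessibility). In the linear
no-interaction case the average causal mediation effect is ACME = a1*b1,
the average direct effect is ADE = b2, and TE = ACME + ADE identically.

Inference is by nonparametric donor-resampling bootstrap with BCa
(bias-corrected and accelerated) intervals, and the error-correlation
sensitivity analysis reports the correlation rho between e_im and e_iy at
which the estimated ACME would change sign; |rho*| >= 0.3 is labelled
robust to unmeasured mediator-outcome confounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from ._utils import substream

MODEL_KINDS = ("I", "II", "III")  # I: X->ATAC->CHiC, II: X->ATAC->RNA, III: X->CHiC->RNA


def genotype_principal_components(dosage: np.ndarray, var_cap: float = 0.99):
    """Centered-dosage principal components retaining cumulative variance <= cap.

    Returns (scores, explained_ratio) with at least one PC; the sign of each
    PC puts its largest-magnitude loading positive, for determinism.
    """
    x = np.asarray(dosage, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("dosage must be donors x variants with >= 2 donors")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("zero-variance dosage matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s > s.max() * 1e-10
    u, s, vt = u[:, keep], s[keep], vt[keep]
    for j in range(vt.shape[0]):  # sign convention
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    evr = s**2 / (s**2).sum()
    n_keep = max(1, int((np.cumsum(evr) <= var_cap).sum()))
    return (u[:, :n_keep] * s[:n_keep]), evr[:n_keep]


def _ols(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular design matrix (collinear treatment/mediator/confounders)")
    return coef


@dataclass
class MediationEstimates:
    acme: float
    ade: float
    te: float
    alpha: np.ndarray  # mediator-model coefficients [a0, a1, a2...]
    beta: np.ndarray  # outcome-model coefficients [b0, b1, b2, b3...]


def fit_mediation(treatment, mediator, outcome, confounders=None) -> MediationEstimates:
    """Least-squares point estimates: ACME = a1*b1, ADE = b2, TE = sum."""
    x = np.asarray(treatment, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    n = x.size
    c = None if confounders is None else np.atleast_2d(np.asarray(confounders, dtype=float).reshape(n, -1))
    cols_m = [np.ones(n), x] + ([c[:, j] for j in range(c.shape[1])] if c is not None else [])
    cols_y = [np.ones(n), m, x] + ([c[:, j] for j in range(c.shape[1])] if c is not None else [])
    if n <= len(cols_y) + 2:
        raise ValueError("too few donors for the outcome design")
    a = _ols(np.column_stack(cols_m), m)
    b = _ols(np.column_stack(cols_y), y)
    acme = float(a[1] * b[1])
    ade = float(b[2])
    return MediationEstimates(acme, ade, acme + ade, a, b)


def _bca_interval(boot: np.ndarray, point: float, jack: np.ndarray, level: float):
    """BCa interval from bootstrap draws and jackknife replicates."""
    b = boot[np.isfinite(boot)]
    if b.size == 0 or np.ptp(b) == 0:
        return (point, point)
    frac = np.clip(np.mean(b < point), 1e-10, 1 - 1e-10)
    z0 = ndtri(frac)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    accel = num / den if den > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for a_ in (alpha, 1.0 - alpha):
        z = z0 + (z0 + ndtri(a_)) / (1.0 - accel * (z0 + ndtri(a_)))
        lo_hi.append(np.quantile(b, np.clip(ndtr(z), 0.0, 1.0)))
    return tuple(lo_hi)


def _boot_pvalue(boot: np.ndarray, n_boot: int) -> float:
    """Two-sided add-one smoothed bootstrap p-value (never 0)."""
    lo = (1.0 + np.sum(boot <= 0)) / (1.0 + n_boot)
    hi = (1.0 + np.sum(boot >= 0)) / (1.0 + n_boot)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class MediationResult:
    acme: float
    ade: float
    te: float
    acme_ci: tuple
    ade_ci: tuple
    te_ci: tuple
    acme_p: float
    ade_p: float
    te_p: float
    classification: str
    n_boot: int
    low_boot_warning: bool = False


class MediationModel(BaseEstimator):
    """Mediation estimator with BCa bootstrap inference.

    model_kind is carried as a label ("I", "II", "III"); the fitted designs
    are identical up to which traits play treatment/mediator/outcome and
    whether accessibility enters as an observed confounder.
    """

    def __init__(self, model_kind="I", n_boot=1000, ci_level=0.95, alpha=0.05, seed=0):
        self.model_kind = model_kind
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.alpha = alpha
        self.seed = seed

    def fit(self, treatment, mediator, outcome, confounders=None):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        x = np.asarray(treatment, dtype=float).ravel()
        m = np.asarray(mediator, dtype=float).ravel()
        y = np.asarray(outcome, dtype=float).ravel()
        n = x.size
        if n < 10:
            raise ValueError("need at least 10 donors for bootstrap inference")
        c = None if confounders is None else np.asarray(confounders, dtype=float).reshape(n, -1)
        est = fit_mediation(x, m, y, c)
        self.estimates_ = est

        rng = substream(self.seed, "mediation_boot", self.model_kind)
        boot = np.empty((self.n_boot, 3))
        for b_ in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                e = fit_mediation(x[idx], m[idx], y[idx], None if c is None else c[idx])
                boot[b_] = (e.acme, e.ade, e.te)
            except ValueError:
                boot[b_] = np.nan
        jack = np.empty((n, 3))
        for i in range(n):
            idx = np.r_[0:i, i + 1 : n]
            e = fit_mediation(x[idx], m[idx], y[idx], None if c is None else c[idx])
            jack[i] = (e.acme, e.ade, e.te)

        cis, ps = [], []
        for j, point in enumerate((est.acme, est.ade, est.te)):
            cis.append(_bca_interval(boot[:, j], point, jack[:, j], self.ci_level))
            ps.append(_boot_pvalue(boot[~np.isnan(boot[:, j]), j], self.n_boot))
        result = MediationResult(
            est.acme, est.ade, est.te, cis[0], cis[1], cis[2], ps[0], ps[1], ps[2],
            classification="", n_boot=self.n_boot, low_boot_warning=self.n_boot < 100,
        )
        result.classification = classify_mediation(result, self.alpha)
        self.result_ = result
        self.boot_ = boot
        return self


def bootstrap_mediation(treatment, mediator, outcome, confounders=None, n_boot=1000,
                        seed=0, **kw) -> MediationResult:
    model = MediationModel(n_boot=n_boot, seed=seed, **kw)
    return model.fit(treatment, mediator, outcome, confounders).result_


def classify_mediation(result: MediationResult, alpha: float = 0.05) -> str:
    """Mediation is declared when both TE and ACME are significant; the ADE
    p-value separates full (> alpha) from partial (<= alpha) mediation."""
    if result.te_p <= alpha and result.acme_p <= alpha:
        return "full" if result.ade_p > alpha else "partial"
    return "none"


@dataclass
class SensitivityCurve:
    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_star: float | None
    robust: bool


def sensitivity_analysis(treatment, mediator, outcome, confounders=None,
                         rho_grid=None) -> SensitivityCurve:
    """ACME as a function of the mediator-outcome error correlation rho.

    Residualising M and Y on [1, X, C] reduces the system to a bivariate
    errors-in-equations problem with closed form for the mediator->outcome
    slope consistent with correlation rho:

      b1(rho) = b1_ols - rho * s_{y|m} / (s_m * sqrt(1 - rho^2))

    where s_m is the sd of the mediator residual and s_{y|m} the residual sd
    of the outcome residual regressed on it. ACME(rho) = a1 * b1(rho);
    ACME(0) equals the point estimate. rho_star is the grid value of
    smallest magnitude where the curve crosses zero.
    """
    if rho_grid is None:
        rho_grid = np.arange(-0.99, 0.991, 0.01)
    rho_grid = np.asarray(rho_grid, dtype=float)
    x = np.asarray(treatment, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    n = x.size
    c = None if confounders is None else np.asarray(confounders, dtype=float).reshape(n, -1)
    est = fit_mediation(x, m, y, c)
    design = np.column_stack([np.ones(n), x] + ([c[:, j] for j in range(c.shape[1])] if c is not None else []))
    rm = m - design @ _ols(design, m)
    ry = y - design @ _ols(design, y)
    s_m2 = rm @ rm / n
    b1_ols = (rm @ ry) / (rm @ rm)
    resid = ry - b1_ols * rm
    s_cond = np.sqrt(resid @ resid / n)
    b1_rho = b1_ols - rho_grid / np.sqrt(1.0 - rho_grid**2) * s_cond / np.sqrt(s_m2)
    acme_rho = est.alpha[1] * b1_rho

    rho_star = None
    order = np.argsort(np.abs(rho_grid), kind="stable")
    signs = np.sign(acme_rho)
    for pos in order:
        if signs[pos] == 0:
            rho_star = float(rho_grid[pos])
            break
        lower = pos - 1 if rho_grid[pos] > 0 else pos + 1
        if 0 <= lower < len(rho_grid) and signs[lower] != 0 and signs[pos] != signs[lower]:
            rho_star = float(rho_grid[pos])
            break
    robust = rho_star is not None and abs(rho_star) >= 0.3
    return SensitivityCurve(rho_grid, acme_rho, rho_star, robust)
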