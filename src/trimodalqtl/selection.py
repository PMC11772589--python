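"""Joint Bayesian variable selection across three molecular traits.

Within a genomic window linking genotyped variants to three traits (promoter
contact, chromatin accessibility, expression), searches model space with
Metropolis-coupled MCMC (parallel tempering) under a conjugate g-prior,
reporting marginal posterior probabilities of inclusion (mPPI), the best
model visited (largest marginal-likelihood score), a Bayesian-FDR selection
at level q, and Bayesian-model-averaged effects with posterior z-scores.

Marginal likelihood for an indicator gamma is the product over the three
traits of the per-trait conjugate g-prior marginal,

  log m(y | gamma) = -(r/2) log(1+g) - ((n-1)/2) log( y'y - g/(1+g) y'H y )

with H the projection onto the selected genotype columns computed through
pivoted QR at effective rank r, which makes the score well defined under
extreme multicollinearity (redundant columns carry no extra fit and no
extra penalty). The model-size prior is independent Bernoulli inclusion
with omega = 1/k, so the expected number of selected variants is 1 with
standard deviation sqrt(1 - 1/k) ~ 1 regardless of window size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import binomtest
from sklearn.base import BaseEstimator

from ._utils import substream

MODALITIES = ("chic", "atac", "rna")


@dataclass
class FilterThresholds:
    """Post-hoc filters: baseline allelic-imbalance floor and minimum
    absolute BMA effect per modality (contact, accessibility, expression)."""

    ai_min: float = 0.4
    beta_min: tuple = (0.006, 0.001, 0.004)


# ---------------------------------------------------------------------------
# window construction


def define_windows(
    bait_intervals: pd.DataFrame,
    peak_intervals: pd.DataFrame,
    variants: pd.DataFrame,
    egene_promoters: pd.DataFrame,
    dpnii_flagged_variants: set | frozenset = frozenset(),
    pad: int = 5_000,
    promoter_exclusion: int = 10_000,
) -> pd.DataFrame:
    """Windows = (bait fragment +/- 5 kb) intersected with (ATAC peak +/- 5 kb).

    Intervals are BED-style 0-based half-open. A window is dropped when any
    contained variant is flagged for DpnII cut-site effects at the bait, or
    lies within 10 kb of the promoter of the bait's eGene.
    """
    for df, name in ((bait_intervals, "bait"), (peak_intervals, "peak")):
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ValueError(f"malformed {name} interval at line {bad[0]}: start >= end")
    prom = egene_promoters.set_index("egene")["pos"] if len(egene_promoters) else pd.Series(dtype=float)
    prom_chrom = egene_promoters.set_index("egene")["chrom"] if len(egene_promoters) else pd.Series(dtype=object)
    rows = []
    for _, bait in bait_intervals.iterrows():
        b_lo, b_hi = bait["start"] - pad, bait["end"] + pad
        peaks = peak_intervals[peak_intervals["chrom"] == bait["chrom"]]
        for _, peak in peaks.iterrows():
            lo = max(b_lo, peak["start"] - pad)
            hi = min(b_hi, peak["end"] + pad)
            if lo >= hi:
                continue
            inside = variants[
                (variants["chrom"] == bait["chrom"]) & (variants["pos"] >= lo) & (variants["pos"] < hi)
            ]
            if inside.empty:
                continue
            if inside["variant_id"].isin(dpnii_flagged_variants).any():
                continue
            egene = bait.get("egene")
            if egene is not None and egene in prom.index and prom_chrom[egene] == bait["chrom"]:
                if (np.abs(inside["pos"] - prom[egene]) <= promoter_exclusion).any():
                    continue
            rows.append(
                {
                    "chrom": bait["chrom"],
                    "start": int(lo),
                    "end": int(hi),
                    "bait_id": bait.get("bait_id", ""),
                    "peak_id": peak.get("peak_id", ""),
                    "egene": egene,
                    "variant_ids": list(inside["variant_id"]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal likelihood


def _projection_fit(x_sel: np.ndarray, y: np.ndarray):
    """Pivoted-QR projection: returns (rank, y'Hy per trait)."""
    if x_sel.shape[1] == 0:
        return 0, np.zeros(y.shape[1])
    q, r, _ = scipy.linalg.qr(x_sel, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x_sel.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    q1 = q[:, :rank]
    proj = q1.T @ y
    return rank, (proj**2).sum(axis=0)


def log_marginal_likelihood(x_std: np.ndarray, y: np.ndarray, gamma, g: float) -> float:
    """Sum over traits of the conjugate g-prior log marginal (up to a shared
    constant); invariant to index order and to duplicated selected columns."""
    idx = sorted(set(int(j) for j in gamma))
    n = x_std.shape[0]
    rank, yhy = _projection_fit(x_std[:, idx], y)
    yty = (y**2).sum(axis=0)
    shrink = g / (1.0 + g)
    resid = yty - shrink * yhy
    return float(-(rank / 2.0) * np.log(1.0 + g) * y.shape[1] - ((n - 1) / 2.0) * np.log(resid).sum())


def _model_size_log_prior(size: int, k: int) -> float:
    omega = 1.0 / k
    return size * np.log(omega) + (k - size) * np.log(1.0 - omega)


# ---------------------------------------------------------------------------
# model search


@dataclass
class SearchResult:
    mppi: np.ndarray
    best_model: tuple
    best_log_ml: float
    visited: dict = field(default_factory=dict)  # model -> cold-chain visit count post burn-in
    log_ml: dict = field(default_factory=dict)  # model -> marginal likelihood score


def search_models(
    x_std: np.ndarray,
    y: np.ndarray,
    n_iter: int = 20_000,
    burn_in: int = 5_000,
    n_chains: int = 3,
    g: float | None = None,
    seed: int = 0,
    temperatures: tuple | None = None,
) -> SearchResult:
    """Metropolis-coupled search over variant-inclusion indicators.

    Moves: symmetric flip (add/delete a uniformly chosen variant) and swap
    (exchange a selected with an unselected variant), plus one exchange
    attempt between a random adjacent temperature pair per iteration.
    mPPI is the inclusion frequency in the cold chain after burn-in; the
    best model is the maximum-marginal-likelihood model visited by any chain.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    n, k = x_std.shape
    g = float(n) if g is None else float(g)
    temps = np.array(temperatures if temperatures is not None else [2.0**j for j in range(n_chains)])
    n_chains = len(temps)
    rng = substream(seed, "guess")

    ml_cache: dict = {}

    def log_ml(model: frozenset) -> float:
        if model not in ml_cache:
            ml_cache[model] = log_marginal_likelihood(x_std, y, model, g)
        return ml_cache[model]

    def score(model: frozenset) -> float:
        return log_ml(model) + _model_size_log_prior(len(model), k)

    states = [frozenset() for _ in range(n_chains)]
    scores = [score(s) for s in states]
    best_model, best_ml = frozenset(), log_ml(frozenset())
    incl_count = np.zeros(k)
    visited: dict = {}
    kept = 0

    for it in range(n_iter):
        for c in range(n_chains):
            cur = states[c]
            # move type drawn independently of the state so the kernel stays
            # symmetric; a swap from the empty/full model is a no-op
            if rng.random() < 0.5:
                j = int(rng.integers(k))  # flip
                prop = cur ^ {j}
            elif 0 < len(cur) < k:  # swap one in, one out
                sel = list(cur)
                unsel = [j for j in range(k) if j not in cur]
                prop = (cur - {sel[int(rng.integers(len(sel)))]}) | {unsel[int(rng.integers(len(unsel)))]}
            else:
                prop = None
            if prop is not None:
                s_prop = score(prop)
                if np.log(rng.random()) < (s_prop - scores[c]) / temps[c]:
                    states[c], scores[c] = prop, s_prop
            if log_ml(states[c]) > best_ml:
                best_ml, best_model = log_ml(states[c]), states[c]
        if n_chains > 1:  # one adjacent-pair exchange attempt
            a = int(rng.integers(n_chains - 1))
            delta = (1.0 / temps[a] - 1.0 / temps[a + 1]) * (scores[a + 1] - scores[a])
            if np.log(rng.random()) < delta:
                states[a], states[a + 1] = states[a + 1], states[a]
                scores[a], scores[a + 1] = scores[a + 1], scores[a]
        if it >= burn_in:
            cold = states[0]
            for j in cold:
                incl_count[j] += 1
            visited[cold] = visited.get(cold, 0) + 1
            kept += 1

    mppi = incl_count / kept
    return SearchResult(mppi, tuple(sorted(best_model)), best_ml, visited, dict(ml_cache))


# ---------------------------------------------------------------------------
# FDR selection and BMA


def fdr_select(mppi: np.ndarray, q: float = 0.05, rule: str = "mean_local_fdr") -> list:
    """Bayesian-FDR selection on sorted mPPI.

    Default rule keeps the largest prefix j (mPPI non-increasing, ties broken
    by variant index) with mean local fdr (1/j) sum_{i<=j} (1-mPPI_(i)) <= q;
    rule="cumulative_sum" uses the unnormalised running sum instead.
    """
    mppi = np.asarray(mppi, dtype=float)
    order = np.lexsort((np.arange(len(mppi)), -mppi))
    lfdr = 1.0 - mppi[order]
    csum = np.cumsum(lfdr)
    if rule == "mean_local_fdr":
        crit = csum / np.arange(1, len(mppi) + 1)
    elif rule == "cumulative_sum":
        crit = csum
    else:
        raise ValueError(f"unknown FDR rule {rule!r}")
    ok = np.nonzero(crit <= q)[0]
    if ok.size == 0:
        return []
    return sorted(order[: ok.max() + 1].tolist())


def bma_effects(visited: dict, x_std: np.ndarray, y: np.ndarray, g: float | None = None):
    """Bayesian model averaging over visited models with visit-count weights.

    Per model, the conditional posterior mean is the g-prior shrinkage of the
    least-squares fit, g/(1+g) * beta_ols, with conditional variance
    g/(1+g) * s^2 * (X'X)^-1 diagonal (s^2 from the g-prior residual sum).
    Excluded coefficients contribute zeros. The posterior z-score is
    E(beta|Y) / sqrt(E(sigma^2(beta)|Y)).
    """
    if not visited:
        raise ValueError("no visited models")
    n, k = x_std.shape
    t = y.shape[1]
    g = float(n) if g is None else float(g)
    shrink = g / (1.0 + g)
    total = sum(visited.values())
    beta = np.zeros((k, t))
    var = np.zeros((k, t))
    for model, count in visited.items():
        w = count / total
        idx = sorted(model)
        if not idx:
            continue
        xs = x_std[:, idx]
        xtx_inv = np.linalg.pinv(xs.T @ xs)
        bols = xtx_inv @ (xs.T @ y)  # (|m|, t)
        yty = (y**2).sum(axis=0)
        a = y.T @ xs  # (t, |m|)
        yhy = np.einsum("tj,jk,tk->t", a, xtx_inv, a)
        s2 = (yty - shrink * yhy) / (n - 1)
        cvar = shrink * np.outer(np.diag(xtx_inv), s2)
        beta[idx] += w * shrink * bols
        var[idx] += w * cvar
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, beta / np.sqrt(var), 0.0)
    if np.any((var == 0) & (beta != 0)):
        raise FloatingPointError("zero posterior variance with nonzero posterior mean")
    return beta, np.sqrt(var), z


# ---------------------------------------------------------------------------
# estimator facade


class TrimodalSelector(BaseEstimator):
    """Parallel-tempered variable selection over one window.

    Fitted attributes: mppi_, best_model_, fdr_set_, bma_beta_, bma_se_,
    zscores_ (all per variant; effect arrays are variants x 3 modalities).
    """

    def __init__(self, n_iter=20_000, burn_in=5_000, n_chains=3, g=None, q=0.05,
                 fdr_rule="mean_local_fdr", seed=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.g = g
        self.q = q
        self.fdr_rule = fdr_rule
        self.seed = seed

    def fit(self, x_std: np.ndarray, y: np.ndarray):
        x_std = np.asarray(x_std, dtype=float)
        y = np.asarray(y, dtype=float)
        res = search_models(
            x_std, y, n_iter=self.n_iter, burn_in=self.burn_in, n_chains=self.n_chains,
            g=self.g, seed=self.seed,
        )
        self.search_ = res
        self.mppi_ = res.mppi
        self.best_model_ = res.best_model
        # null best model: no associations declared
        self.fdr_set_ = [] if not res.best_model else fdr_select(res.mppi, self.q, self.fdr_rule)
        self.bma_beta_, self.bma_se_, self.zscores_ = bma_effects(
            res.visited, x_std, y, g=self.g if self.g is not None else float(x_std.shape[0])
        )
        return self

    def summary(self, variant_ids=None) -> pd.DataFrame:
        k = len(self.mppi_)
        ids = variant_ids if variant_ids is not None else [f"var{j}" for j in range(k)]
        df = pd.DataFrame({"variant_id": ids, "mppi": self.mppi_})
        df["in_best_model"] = [j in self.best_model_ for j in range(k)]
        df["fdr_selected"] = [j in self.fdr_set_ for j in range(k)]
        for m, name in enumerate(MODALITIES):
            df[f"beta_{name}"] = self.bma_beta_[:, m]
            df[f"se_{name}"] = self.bma_se_[:, m]
            df[f"z_{name}"] = self.zscores_[:, m]
        return df


# ---------------------------------------------------------------------------
# post-hoc filters and concordance


def finalize_trimodal(
    selection: pd.DataFrame,
    filters: FilterThresholds | None = None,
    bias_table: pd.DataFrame | None = None,
) -> dict:
    """Apply post-hoc filters to FDR-selected variants and score concordance.

    Drops variants with baseline AI < ai_min (missing bias entries are
    dropped with a reason code) or any |beta| below the per-modality floor;
    surviving variants are concordant when their three BMA effects share a
    sign. Returns the final table plus the concordant fraction tested
    against the 25% null for three independent modalities.
    """
    filters = filters or FilterThresholds()
    df = selection[selection["fdr_selected"]].copy()
    reasons = []
    ai = None
    if bias_table is not None:
        ai = bias_table.set_index("variant_id")["ai0"]
    keep = []
    for _, row in df.iterrows():
        if ai is not None:
            if row["variant_id"] not in ai.index:
                reasons.append((row["variant_id"], "missing_bias"))
                continue
            if ai[row["variant_id"]] < filters.ai_min:
                reasons.append((row["variant_id"], "discarded_bias"))
                continue
        betas = [row[f"beta_{m}"] for m in MODALITIES]
        if any(abs(b) < bmin for b, bmin in zip(betas, filters.beta_min)):
            reasons.append((row["variant_id"], "small_effect"))
            continue
        keep.append(row)
    final = pd.DataFrame(keep).reset_index(drop=True)
    if len(final):
        signs = np.sign(final[[f"beta_{m}" for m in MODALITIES]].to_numpy())
        final["concordant"] = np.all(signs == signs[:, [0]], axis=1)
        frac = float(final["concordant"].mean())
        test = binomtest(int(final["concordant"].sum()), len(final), 0.25, alternative="greater")
        pval = float(test.pvalue)
    else:
        final["concordant"] = pd.Series(dtype=bool)
        frac, pval = np.nan, np.nan
    return {
        "final": final,
        "dropped": pd.DataFrame(reasons, columns=["variant_id", "reason"]),
        "concordant_fraction": frac,
        "concordance_null": 0.25,
        "binomial_p": pval,
    }
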