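"""Synthetic cohort generator.

Emulates the statistical structure of a small multi-omic QTL cohort:
diploid donors with Hardy-Weinberg genotypes and imputation-probability
noise; library-size-offset negative-binomial totals whose mean depends on
genotype through the allelic fold change; beta-binomial allele-specific
counts in heterozygotes with a reference-bias baseline; windows of
standardized genotypes driving three correlated variance-stabilized traits;
mediation triplets with known path coefficients; long-tailed TF-perturbation
score backgrounds; and a toy enhancer-gene locus whose expression is built
from gene-level activity-by-contact scores at a planted inclusion threshold.

Every generator is a pure function of (config, seed): RNG sub-streams are
derived by stable hashing of (stage, feature id), so outputs are
bit-identical for identical configs regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import logistic, logit, substream


@dataclass
class MediationParams:
    """True path coefficients for the mediation triplet.

    alpha1: treatment -> mediator; beta1: mediator -> outcome;
    beta2: direct treatment -> outcome; rho: correlation of the two error
    terms (an unobserved mediator-outcome confounder); sigma_m / sigma_y:
    error scales.
    """

    alpha1: float = 0.5
    beta1: float = 0.4
    beta2: float = 0.3
    rho: float = 0.0
    sigma_m: float = 1.0
    sigma_y: float = 1.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_donors: int = 34
    maf: float = 0.25
    mean_depth: float = 100.0
    log_afc: float = 0.0
    nb_overdispersion: float = 8.0
    bb_overdispersion: float = 20.0
    baseline_ai: float = 0.5
    gp_noise: float = 50.0
    window_k: int = 8
    effect_matrix: np.ndarray | None = None  # (window_k, 3) true effects on (CHiC, ATAC, RNA)
    resid_corr: np.ndarray | None = None  # 3x3 residual correlation
    mediation: MediationParams = field(default_factory=MediationParams)
    libsize_sigma: float = 0.3  # log-normal spread of library sizes around 1

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.gp_noise <= 0:
            raise ValueError("gp_noise must be positive")
        if not (0.0 < self.baseline_ai < 1.0):
            raise ValueError("baseline_ai must lie in (0, 1)")
        if self.nb_overdispersion <= 0 or self.bb_overdispersion <= 0:
            raise ValueError("overdispersion parameters must be positive")
        if abs(self.mediation.rho) >= 1:
            raise ValueError("|mediation.rho| must be < 1")
        if self.effect_matrix is not None:
            self.effect_matrix = np.atleast_2d(np.asarray(self.effect_matrix, dtype=float))
            if self.effect_matrix.shape != (self.window_k, 3):
                raise ValueError("effect_matrix must have shape (window_k, 3)")
        if self.resid_corr is not None:
            r = np.asarray(self.resid_corr, dtype=float)
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("resid_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() <= 0:
                raise ValueError("resid_corr must be positive definite")
            self.resid_corr = r


@dataclass
class GenotypePanel:
    """Variants x donors: true dosages, hard calls and genotype-class probabilities."""

    variant_ids: list
    dosage: np.ndarray  # (k, n) true alt-allele dosage in {0,1,2}
    gp: np.ndarray  # (k, n, 3) per-donor genotype-class probabilities
    hard_call: np.ndarray  # (k, n) argmax class

    @property
    def n_donors(self) -> int:
        return self.dosage.shape[1]


@dataclass
class FeatureCounts:
    feature_id: str
    total: np.ndarray  # (n,) total counts per donor
    alt: np.ndarray  # (n,) alt-allele counts; NaN where not heterozygous-informative
    libsize: np.ndarray  # (n,) positive library-size offsets


@dataclass
class AnalysisWindow:
    window_id: str
    x_std: np.ndarray  # (n, k) standardized genotypes
    y: np.ndarray  # (n, 3) mean-centered traits (CHiC, ATAC, RNA)
    dosage: np.ndarray  # (n, k) raw dosages
    true_effects: np.ndarray  # (k, 3)


@dataclass
class MediationDataset:
    treatment: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray
    true_acme: float
    true_rho: float


def simulate_genotypes(config: SimulationConfig, n_variants: int | None = None) -> GenotypePanel:
    """Hardy-Weinberg genotypes with Dirichlet imputation blur.

    Class probabilities are Dirichlet with concentration gp_noise on the true
    class (plus 0.5 on every class to keep them proper); gp_noise = inf gives
    exact one-hot probabilities.
    """
    if config.n_donors < 2:
        raise ValueError("need at least 2 donors")
    k = config.window_k if n_variants is None else n_variants
    dosage = np.empty((k, config.n_donors), dtype=int)
    gp = np.empty((k, config.n_donors, 3))
    for v in range(k):
        rng = substream(config.seed, "genotypes", v)
        dosage[v] = rng.binomial(2, config.maf, size=config.n_donors)
        onehot = np.eye(3)[dosage[v]]
        if np.isinf(config.gp_noise):
            gp[v] = onehot
        else:
            conc = config.gp_noise * onehot + 0.5
            for i in range(config.n_donors):
                gp[v, i] = rng.dirichlet(conc[i])
    hard = gp.argmax(axis=2)
    ids = [f"var{v}" for v in range(k)]
    return GenotypePanel(ids, dosage, gp, hard)


def simulate_count_feature(
    panel: GenotypePanel, config: SimulationConfig, variant_index: int = 0, feature_id: str | None = None
) -> FeatureCounts:
    """Genotype-dependent NB totals plus beta-binomial allelic counts in hets.

    NB mean is mean_depth * libsize * (2 - g + g*e^beta)/2, so the hom-alt /
    hom-ref mean ratio is exactly exp(log_afc). Heterozygote alt counts are
    BetaBinomial(c, pi, theta) with pi = logistic(logit(AI0) + beta).
    """
    if panel.dosage.size == 0:
        raise ValueError("empty genotype panel")
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    fid = feature_id or f"feature{variant_index}"
    rng = substream(config.seed, "counts", fid)
    g = panel.dosage[variant_index]
    n = g.size
    libsize = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
    beta = config.log_afc
    genofac = (2.0 - g + g * np.exp(beta)) / 2.0
    mu = config.mean_depth * libsize * genofac
    phi = config.nb_overdispersion
    total = rng.negative_binomial(phi, phi / (phi + mu))
    alt = np.full(n, np.nan)
    het = g == 1
    if het.any():
        pi = logistic(logit(config.baseline_ai) + beta)
        theta = config.bb_overdispersion
        p = rng.beta(pi * theta, (1.0 - pi) * theta, size=het.sum())
        alt[het] = rng.binomial(total[het], p)
    return FeatureCounts(fid, total.astype(int), alt, libsize)


def simulate_trimodal_window(config: SimulationConfig, window_id: str = "window0") -> AnalysisWindow:
    """Three correlated mean-centered traits driven by standardized genotypes.

    Y = X_std @ B + E with E rows drawn with covariance resid_corr.
    """
    b = config.effect_matrix
    if b is None:
        b = np.zeros((config.window_k, 3))
    corr = config.resid_corr if config.resid_corr is not None else np.eye(3)
    panel = simulate_genotypes(config)
    rng = substream(config.seed, "window", window_id)
    x = panel.dosage.T.astype(float)  # (n, k)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic-in-sample columns stay centered but unscaled
    x_std = (x - x.mean(axis=0)) / sd
    chol = np.linalg.cholesky(corr)
    e = rng.standard_normal((config.n_donors, 3)) @ chol.T
    y = x_std @ b + e
    y = y - y.mean(axis=0)
    return AnalysisWindow(window_id, x_std, y, x, b)


def simulate_mediation(config: SimulationConfig, n: int | None = None) -> MediationDataset:
    """Linear mediation triplet with known ACME = alpha1*beta1.

    M = alpha1*X + eps_m;  Y = beta1*M + beta2*X + eps_y;
    corr(eps_m, eps_y) = rho.
    """
    p = config.mediation
    if abs(p.rho) >= 1:
        raise ValueError("|rho| must be < 1")
    n = config.n_donors if n is None else n
    rng = substream(config.seed, "mediation")
    x = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps_m = p.sigma_m * z1
    eps_y = p.sigma_y * (p.rho * z1 + np.sqrt(1.0 - p.rho**2) * z2)
    m = p.alpha1 * x + eps_m
    y = p.beta1 * m + p.beta2 * x + eps_y
    return MediationDataset(x, m, y, true_acme=p.alpha1 * p.beta1, true_rho=p.rho)


def simulate_tf_background(
    n_variants: int,
    config: SimulationConfig,
    tools: tuple = ("deepsea", "enformer"),
    tfs: tuple = ("SPI1", "CEBPB", "STAT3"),
    spike_prob: float = 0.05,
    spike_scale: float = 2.0,
    noise_scale: float = 0.01,
) -> pd.DataFrame:
    """Long-tailed background panels of TF-perturbation scores.

    Mixture of near-zero mass (most random variants do nothing) and rare
    large signed effects, per (tool, TF).
    """
    if n_variants < 100:
        raise ValueError("background needs at least 100 variants")
    rows = []
    for tool in tools:
        for tf in tfs:
            rng = substream(config.seed, "tf_background", tool, tf)
            spike = rng.random(n_variants) < spike_prob
            score = rng.normal(0.0, noise_scale, size=n_variants)
            big = rng.exponential(spike_scale, size=n_variants) * rng.choice([-1.0, 1.0], size=n_variants)
            score[spike] = big[spike]
            rows.append(pd.DataFrame({"tool": tool, "tf": tf, "variant_id": np.arange(n_variants), "score": score}))
    return pd.concat(rows, ignore_index=True)


def simulate_abc_locus(
    config: SimulationConfig,
    n_genes: int = 30,
    enh_per_gene: int = 6,
    planted_threshold: float = 0.3,
    noise_sd: float = 0.05,
) -> dict:
    """Toy enhancer-gene locus for threshold calibration.

    Expression is generated from gene-level ABC computed at the planted
    enhancer-inclusion threshold plus log-normal noise, so calibrating the
    threshold against expression should recover it.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = substream(config.seed, "abc_locus")
    rows = []
    for gidx in range(n_genes):
        gene = f"gene{gidx}"
        act = rng.lognormal(0.0, 1.0, size=enh_per_gene)
        con = rng.lognormal(0.0, 1.0, size=enh_per_gene)
        dist = rng.uniform(5_000, 4_000_000, size=enh_per_gene)
        if gidx % 5 == 0:  # occasional enhancer outside the 5 Mb window
            dist[-1] = 6_000_000
        for e in range(enh_per_gene):
            rows.append(
                {
                    "gene_id": gene,
                    "enhancer_id": f"{gene}_enh{e}",
                    "activity": act[e],
                    "contact": con[e],
                    "distance": dist[e],
                }
            )
    pairs = pd.DataFrame(rows)

    from .abc import gene_level_abc  # local import: abc builds on nothing here

    gene_scores = gene_level_abc(pairs, planted_threshold)
    expr = gene_scores * np.exp(rng.normal(0.0, noise_sd, size=len(gene_scores)))
    expression = pd.Series(expr.to_numpy(), index=gene_scores.index, name="expression")
    return {"pairs": pairs, "expression": expression, "planted_threshold": planted_threshold}
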