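"""Variant effects on predicted TF binding and on binding motifs.

Two complementary read-outs for whether a QTL allele perturbs transcription-
factor binding:

1. Deep-learning allele scores. For each (tool, TF, training dataset) pair
   with predicted ChIP signal for both alleles, the SNP activity difference
   SAD = alt - ref and ratio SAR = log2(alt+1) - log2(ref+1) combine into a
   perturbation score max_i(SAD_i * SAR_i) over datasets. A variant is
   called perturbing for a TF when its score exceeds the nearest-rank 99th
   percentile of an empirical background panel, and a consensus call
   requires exceedance under both tools.

2. Motif disruption. Position frequency matrices (JASPAR format) are turned
   into information-content-weighted score matrices against a flat
   background; each allele's sequence is scanned over both strands and all
   offsets, match p-values are computed by exact discrete convolution of the
   per-position score distributions, and a "strong" disruption requires a
   motif match at p <= 1e-4 for either allele plus an absolute difference in
   normalized match scores of at least 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# deep-learning allele scores


def sad_sar(ref_score: float, alt_score: float) -> tuple:
    """SNP activity difference and log2 ratio (add-one)."""
    if ref_score < 0 or alt_score < 0:
        raise ValueError("predicted signals must be non-negative")
    sad = alt_score - ref_score
    sar = np.log2(alt_score + 1.0) - np.log2(ref_score + 1.0)
    return float(sad), float(sar)


def perturbation_score(ref_scores, alt_scores) -> float:
    """max over training datasets of SAD_i * SAR_i."""
    ref_scores = np.asarray(ref_scores, dtype=float)
    alt_scores = np.asarray(alt_scores, dtype=float)
    if ref_scores.size == 0 or ref_scores.shape != alt_scores.shape:
        raise ValueError("need at least one dataset with both allele scores")
    products = [np.prod(sad_sar(r, a)) for r, a in zip(ref_scores, alt_scores)]
    return float(np.max(products))


def nearest_rank_percentile(values, pct: float = 99.0) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * N)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty background")
    rank = int(np.ceil(pct / 100.0 * v.size))
    return float(v[max(rank, 1) - 1])


@dataclass
class PerturbationCall:
    variant_id: str
    tf: str
    scores: dict  # tool -> score
    thresholds: dict  # tool -> background 99th percentile (None if missing)
    exceeds: dict  # tool -> bool or None
    consensus: bool | None  # None when a tool's background is missing


def call_perturbation(variant_id: str, tf: str, scores_by_tool: dict,
                      background_by_tool: dict, pct: float = 99.0,
                      min_background: int = 100) -> PerturbationCall:
    """Two-tool consensus call against empirical background percentiles."""
    thresholds, exceeds = {}, {}
    for tool, score in scores_by_tool.items():
        bg = background_by_tool.get(tool)
        if bg is None or len(bg) < min_background:
            thresholds[tool] = None
            exceeds[tool] = None
            continue
        thr = nearest_rank_percentile(bg, pct)
        thresholds[tool] = thr
        exceeds[tool] = bool(score > thr)
    flags = list(exceeds.values())
    consensus = None if (len(flags) < 2 or any(f is None for f in flags)) else all(flags)
    return PerturbationCall(variant_id, tf, dict(scores_by_tool), thresholds, exceeds, consensus)


# ---------------------------------------------------------------------------
# motif models


@dataclass
class MotifModel:
    """Information-content-weighted PWM against a flat background.

    weights[b, i] = p[b, i] * IC_i with p the pseudocounted column
    probabilities and IC_i = 2 + sum_b p log2 p the column information
    content in bits; normalized match scores rescale the attainable range
    to [0, 1].
    """

    name: str
    pfm: np.ndarray  # (4, width) counts or probabilities, rows A,C,G,T
    pseudocount: float = 0.8
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        pfm = np.asarray(self.pfm, dtype=float)
        if pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        # pseudocount distributed by the flat background
        counts = pfm + self.pseudocount / 4.0
        p = counts / counts.sum(axis=0)
        ic = 2.0 + (p * np.log2(p)).sum(axis=0)
        self.pfm = pfm
        self.weights = p * ic

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def normalize(self, raw) -> float:
        return float((raw - self.min_score) / (self.max_score - self.min_score))

    @classmethod
    def from_jaspar(cls, path_or_handle, **kw) -> "MotifModel":
        from Bio import motifs

        handle = open(path_or_handle) if isinstance(path_or_handle, str) else path_or_handle
        try:
            m = motifs.read(handle, "jaspar")
        finally:
            if isinstance(path_or_handle, str):
                handle.close()
        pfm = np.array([m.counts[b] for b in _BASES], dtype=float)
        return cls(m.name or "motif", pfm, **kw)


def _encode(seq: str) -> np.ndarray:
    idx = np.frompyfunc(lambda ch: _BASES.find(ch), 1, 1)(np.array(list(seq.upper())))
    return idx.astype(int)


def best_match(model: MotifModel, seq: str):
    """Best normalized IC-weighted score over both strands and all offsets.

    Positions with ambiguous bases are skipped (flagged). Returns
    (normalized score, offset, strand, skipped_ambiguous).
    """
    w = model.width
    if len(seq) < w:
        raise ValueError("motif wider than sequence")
    skipped = False
    best = (-np.inf, 0, "+")
    for strand, s in (("+", seq.upper()), ("-", seq.upper().translate(_COMP)[::-1])):
        enc = _encode(s)
        for off in range(len(s) - w + 1):
            window = enc[off : off + w]
            if (window < 0).any():
                skipped = True
                continue
            raw = model.weights[window, np.arange(w)].sum()
            norm = model.normalize(raw)
            if norm > best[0]:
                best = (norm, off, strand)
    if not np.isfinite(best[0]):
        raise ValueError("no unambiguous window to score")
    return best[0], best[1], best[2], skipped


def binned_position_scores(model: MotifModel, granularity: float = 1e-3) -> np.ndarray:
    """Per-position normalized score contributions as integer granularity bins.

    The p-value is defined on this discretised scale (1e-3 steps on the
    normalized score), which makes the convolution exactly enumerable.
    """
    span = model.max_score - model.min_score
    contrib = (model.weights - model.weights.min(axis=0)) / span  # (4, w)
    return np.round(contrib / granularity).astype(int)


def match_pvalue(model: MotifModel, norm_score: float, granularity: float = 1e-3) -> float:
    """P(window score >= observed) for one flat-background window.

    Exact discrete convolution of the per-position binned score
    distributions; the observed normalized score is mapped onto the same
    integer grid (clamped to the attainable maximum so a perfect match
    keeps its exact enumeration probability).
    """
    bins = binned_position_scores(model, granularity)
    max_sum = int(bins.max(axis=0).sum())
    pmf = np.ones(1)
    for i in range(model.width):
        col = np.zeros(bins[:, i].max() + 1)
        for b in range(4):
            col[bins[b, i]] += 0.25
        pmf = np.convolve(pmf, col)
    obs = min(int(round(norm_score / granularity)), max_sum)
    return float(pmf[max(obs, 0):].sum())


@dataclass
class MotifHit:
    motif: str
    score_ref: float
    score_alt: float
    p_ref: float
    p_alt: float
    delta: float
    strong: bool
    skipped_ambiguous: bool = False


def motif_allele_effect(model: MotifModel, ref_seq: str, alt_seq: str,
                        p_thresh: float = 1e-4, delta_min: float = 0.7) -> MotifHit:
    """Allelic motif disruption: per-allele best match and score difference.

    strong iff (either allele matches at p <= p_thresh) and
    |score_ref - score_alt| >= delta_min.
    """
    if len(ref_seq) != len(alt_seq):
        raise ValueError("allele sequences must have equal length")
    diff = [i for i, (a, b) in enumerate(zip(ref_seq.upper(), alt_seq.upper())) if a != b]
    if len(diff) != 1:
        raise ValueError("allele sequences must differ at exactly one position")
    s_ref, _, _, sk1 = best_match(model, ref_seq)
    s_alt, _, _, sk2 = best_match(model, alt_seq)
    p_ref = match_pvalue(model, s_ref)
    p_alt = match_pvalue(model, s_alt)
    delta = s_ref - s_alt
    strong = (min(p_ref, p_alt) <= p_thresh) and (abs(delta) >= delta_min)
    return MotifHit(model.name, s_ref, s_alt, p_ref, p_alt, delta, strong, sk1 or sk2)
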