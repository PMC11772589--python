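"""Stage orchestration: validate inputs, run stages in dependency order,
write reproducible TSV/JSON outputs stamped with the config hash and seed."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import countqtl, enrichment, mediation, selection, simulate
from . import io as io_mod
from ._utils import substream

STAGE_ORDER = ["simulate", "callqtl", "enrich", "guess", "mediate", "tfscore", "abc"]
STAGE_DEPS = {
    "callqtl": ["simulate"],
    "enrich": ["callqtl"],
    "guess": ["simulate"],
    "mediate": ["guess"],
    "tfscore": ["simulate"],
    "abc": ["simulate"],
}


@dataclass
class RunConfig:
    stages: list
    outdir: str
    seed: int = 0
    n_donors: int = 34
    n_features: int = 20
    maf: float = 0.25
    mean_depth: float = 100.0
    log_afc: float = 0.0
    input_paths: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=lambda: {"n_warmup": 500, "n_draws": 500, "n_chains": 2})
    guess: dict = field(default_factory=lambda: {"n_iter": 4000, "burn_in": 1000, "n_chains": 3})
    thresholds: dict = field(
        default_factory=lambda: {
            "q": 0.05, "ci": 0.99, "ai_min": 0.4, "pct": 99.0,
            "delta_min": 0.7, "p_thresh": 1e-4,
        }
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_inputs(config: RunConfig) -> dict:
    """Existence, donor-ID consistency and BED sanity checks; returns a report."""
    report = {"errors": [], "files": {}}
    for key, path in config.input_paths.items():
        if not os.path.exists(path):
            report["errors"].append(f"missing file for {key}: {path}")
            continue
        if path.endswith(".bed"):
            try:
                df = io_mod.read_bed(path)
                io_mod.check_bed_sorted(df, path)
                report["files"][key] = len(df)
            except ValueError as exc:
                report["errors"].append(str(exc))
        elif path.endswith(".tsv"):
            report["files"][key] = len(pd.read_csv(path, sep="\t"))
        else:
            report["files"][key] = os.path.getsize(path)
    counts_path = config.input_paths.get("counts")
    vcf_path = config.input_paths.get("vcf")
    if counts_path and vcf_path and os.path.exists(counts_path) and os.path.exists(vcf_path):
        import cyvcf2

        vcf_donors = set(cyvcf2.VCF(vcf_path).samples)
        count_donors = set(pd.read_csv(counts_path, sep="\t").columns) - {"feature_id"}
        extra = sorted(count_donors - vcf_donors)
        if extra:
            report["errors"].append(f"donors in counts but not in VCF: {', '.join(extra)}")
    report["ok"] = not report["errors"]
    return report


def _resolve_stages(requested: list) -> list:
    resolved: list = []

    def add(stage):
        for dep in STAGE_DEPS.get(stage, []):
            add(dep)
        if stage not in resolved:
            resolved.append(stage)

    for s in requested:
        add(s)
    return sorted(resolved, key=STAGE_ORDER.index)


def run_pipeline(config: RunConfig, strict_stages: bool = False) -> dict:
    """Execute requested stages in dependency order on the synthetic cohort.

    With strict_stages=True a stage whose dependency outputs are absent
    raises instead of recomputing them.
    """
    os.makedirs(config.outdir, exist_ok=True)
    if strict_stages:
        for s in config.stages:
            for dep in STAGE_DEPS.get(s, []):
                if dep not in config.stages and not os.path.exists(
                    os.path.join(config.outdir, f"{dep}.done")
                ):
                    raise RuntimeError(f"stage {s!r} requires outputs of {dep!r}")
    stages = _resolve_stages(config.stages)
    meta = {"config_hash": config.digest(), "seed": config.seed, "stages": stages}
    state: dict = {}
    for stage in stages:
        runner = _RUNNERS[stage]
        try:
            outputs = runner(config, state)
        except Exception as exc:  # halt with stage name attached
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        meta[stage] = outputs
        with open(os.path.join(config.outdir, f"{stage}.done"), "w") as fh:
            fh.write(config.digest() + "\n")
    with open(os.path.join(config.outdir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return meta


def _stage_simulate(config: RunConfig, state: dict) -> dict:
    sim = simulate.SimulationConfig(
        seed=config.seed, n_donors=config.n_donors, maf=config.maf,
        mean_depth=config.mean_depth, log_afc=config.log_afc,
    )
    panel = simulate.simulate_genotypes(sim, n_variants=config.n_features)
    donors = io_mod.donor_names(config.n_donors)
    vcf_path = os.path.join(config.outdir, "genotypes.vcf")
    io_mod.write_vcf(panel, vcf_path)
    features = [simulate.simulate_count_feature(panel, sim, v) for v in range(config.n_features)]
    totals = pd.DataFrame([f.total for f in features], columns=donors)
    totals.insert(0, "feature_id", [f.feature_id for f in features])
    alts = pd.DataFrame([f.alt for f in features], columns=donors)
    alts.insert(0, "feature_id", [f.feature_id for f in features])
    libs = pd.DataFrame([f.libsize for f in features], columns=donors)
    libs.insert(0, "feature_id", [f.feature_id for f in features])
    io_mod.write_count_tsv(totals, os.path.join(config.outdir, "counts.tsv"))
    io_mod.write_count_tsv(alts, os.path.join(config.outdir, "alt_counts.tsv"))
    io_mod.write_count_tsv(libs, os.path.join(config.outdir, "libsizes.tsv"))
    window = simulate.simulate_trimodal_window(sim)
    np.savetxt(os.path.join(config.outdir, "window_x.tsv"), window.x_std, delimiter="\t")
    np.savetxt(os.path.join(config.outdir, "window_y.tsv"), window.y, delimiter="\t")
    with open(os.path.join(config.outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(
            {"seed": config.seed, "n_donors": config.n_donors, "maf": config.maf,
             "mean_depth": config.mean_depth, "log_afc": config.log_afc,
             "config_hash": config.digest()}, fh)
    state.update(panel=panel, sim=sim, features=features, window=window)
    return {"vcf": vcf_path, "n_features": config.n_features}


def _stage_callqtl(config: RunConfig, state: dict) -> dict:
    rows = []
    for v, feat in enumerate(state["features"]):
        geno = countqtl.GenotypePosterior.from_panel(state["panel"], v)
        model = countqtl.CountQTLModel(seed=config.seed, **config.sampler)
        model.fit(feat, geno)
        fit = model.fit_
        rows.append(
            {
                "feature_id": feat.feature_id, "variant_id": state["panel"].variant_ids[v],
                "post_mean": fit.post_mean, "post_sd": fit.post_sd,
                "ci99_lo": fit.ci99[0], "ci99_hi": fit.ci99[1], "rhat": fit.rhat,
                "afc": fit.afc if fit.status == "ok" else np.nan,
                "approx_pp": fit.approx_pp if fit.status == "ok" else np.nan,
                "decision": model.decision_,
                "total_reads": int(feat.total.sum()),
            }
        )
    df = pd.DataFrame(rows)
    path = os.path.join(config.outdir, "qtl_calls.tsv")
    df.to_csv(path, sep="\t", index=False)
    state["qtl_calls"] = df
    return {"table": path, "n_significant": int((df["decision"] == "significant").sum())}


def _stage_enrich(config: RunConfig, state: dict) -> dict:
    calls = state["qtl_calls"].dropna(subset=["approx_pp"]).reset_index(drop=True)
    if len(calls) < 4:
        return {"skipped": "too few fitted features"}
    rng = substream(config.seed, "enrich_labels")
    candidates = calls[["variant_id", "approx_pp", "total_reads"]].copy()
    n_eqtl = max(2, len(calls) // 4)
    is_eqtl = np.zeros(len(calls), dtype=bool)
    is_eqtl[rng.choice(len(calls), n_eqtl, replace=False)] = True
    candidates["is_eqtl"] = is_eqtl
    n_bins = max(1, min(4, len(calls) // 8))
    res = enrichment.enrichment_pvalue(candidates, n_samples=1000, n_bins=n_bins,
                                       seed=config.seed)
    out = {"observed": res.observed_stat, "p": res.p_one_sided, "n_samples": res.n_samples,
           "seed": config.seed}
    with open(os.path.join(config.outdir, "enrichment.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _stage_guess(config: RunConfig, state: dict) -> dict:
    window = state["window"]
    sel = selection.TrimodalSelector(seed=config.seed, q=config.thresholds["q"], **config.guess)
    sel.fit(window.x_std, window.y)
    df = sel.summary()
    path = os.path.join(config.outdir, "trimodal.tsv")
    df.to_csv(path, sep="\t", index=False)
    state["selector"], state["trimodal"] = sel, df
    return {"table": path, "best_model": list(sel.best_model_), "fdr_set": list(sel.fdr_set_)}


def _stage_mediate(config: RunConfig, state: dict) -> dict:
    window = state["window"]
    pcs, _ = mediation.genotype_principal_components(window.dosage)
    rows = []
    for j in range(pcs.shape[1]):
        for kind, (m_idx, y_idx, conf_idx) in {"I": (1, 0, None), "II": (1, 2, None),
                                               "III": (0, 2, 1)}.items():
            conf = None if conf_idx is None else window.y[:, conf_idx]
            model = mediation.MediationModel(model_kind=kind, n_boot=200, seed=config.seed)
            model.fit(pcs[:, j], window.y[:, m_idx], window.y[:, y_idx], conf)
            r = model.result_
            sens = mediation.sensitivity_analysis(pcs[:, j], window.y[:, m_idx],
                                                  window.y[:, y_idx], conf)
            rows.append({"pc": j + 1, "model": kind, "acme": r.acme, "ade": r.ade, "te": r.te,
                         "acme_p": r.acme_p, "ade_p": r.ade_p, "te_p": r.te_p,
                         "classification": r.classification, "rho_star": sens.rho_star})
    df = pd.DataFrame(rows)
    path = os.path.join(config.outdir, "mediation.tsv")
    df.to_csv(path, sep="\t", index=False)
    return {"table": path, "n_models": len(df)}


def _stage_tfscore(config: RunConfig, state: dict) -> dict:
    from . import tf as tf_mod

    sim = state["sim"]
    background = simulate.simulate_tf_background(1000, sim)
    rng = substream(config.seed, "tfscore_query")
    rows = []
    for tf_name in background["tf"].unique():
        by_tool = {t: g["score"].to_numpy() for t, g in background[background["tf"] == tf_name].groupby("tool")}
        score = {t: float(rng.normal(0, 1)) for t in by_tool}
        call = tf_mod.call_perturbation("query_variant", tf_name, score, by_tool,
                                        pct=config.thresholds["pct"])
        rows.append({"tf": tf_name, **{f"score_{t}": s for t, s in call.scores.items()},
                     **{f"threshold_{t}": th for t, th in call.thresholds.items()},
                     "consensus": call.consensus})
    df = pd.DataFrame(rows)
    path = os.path.join(config.outdir, "tf_calls.tsv")
    df.to_csv(path, sep="\t", index=False)
    return {"table": path}


def _stage_abc(config: RunConfig, state: dict) -> dict:
    locus = simulate.simulate_abc_locus(state["sim"])
    res = abc_mod.calibrate_threshold(
        locus["pairs"], locus["expression"], grid=np.arange(0.0, 0.51, 0.01),
        n_perm=500, seed=config.seed,
    )
    curve = pd.DataFrame({"threshold": res.threshold_grid, "pearson_r": res.pearson_r})
    curve.to_csv(os.path.join(config.outdir, "abc_curve.tsv"), sep="\t", index=False)
    out = {"best_threshold": res.best_threshold, "best_r": res.best_r,
           "permutation_p": res.permutation_p, "n_perm": res.n_perm, "seed": config.seed}
    with open(os.path.join(config.outdir, "abc_calibration.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    return out


_RUNNERS = {
    "simulate": _stage_simulate,
    "callqtl": _stage_callqtl,
    "enrich": _stage_enrich,
    "guess": _stage_guess,
    "mediate": _stage_mediate,
    "tfscore": _stage_tfscore,
    "abc": _stage_abc,
}
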