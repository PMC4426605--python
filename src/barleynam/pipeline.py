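"""Configuration-driven orchestration of the analysis stages.

A run config is a nested key-value (YAML) document naming the stages to
execute, their parameters and the master seed. Every stage's random draws
descend from the master seed through named substreams, so re-running with
the same config is bit-identical and changing one stage's stream does not
perturb the others. Stage outputs are TSV files in the run directory with a
provenance header; a log records wall time and record counts per stage.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval, io, simulate
from .gwas import ModelB, grid_pairs
from .trial import MultiEnvTrial

STAGE_ORDER = ["simulate", "qc", "phenostats", "gwas", "epistasis", "haplo",
               "predict", "cv", "report"]

#: named substreams off the master seed, one per stage
_STREAMS = {name: i for i, name in enumerate(STAGE_ORDER)}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", ["simulate", "phenostats", "gwas", "report"])
    unknown = [s for s in cfg["stages"] if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    cfg["stages"] = sorted(set(cfg["stages"]), key=STAGE_ORDER.index)
    for key in ("genotypes", "map", "phenotypes", "families", "haplotypes"):
        p = cfg.get("inputs", {}).get(key)
        if p and not Path(p).exists():
            raise ConfigError(f"input path does not exist: {p}")
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master_seed), _STREAMS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def run_pipeline(config: dict | str | Path, outdir) -> Path:
    """Execute the configured stages in order; outputs and a JSON log land
    in ``outdir``. A stage failure halts the run with the stage named;
    partial outputs are retained."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = io.config_hash({k: str(v) for k, v in config.items()})
    prov = {"seed": seed, "config_hash": chash}
    log = []
    state: dict = {}
    for stage in config["stages"]:
        t0 = time.time()
        try:
            n_records = _STAGE_FUNCS[stage](config, state, outdir, prov)
        except Exception as err:
            _write_log(outdir, log, failed=stage, error=str(err))
            raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        log.append({"stage": stage, "seconds": round(time.time() - t0, 3),
                    "records": n_records})
    _write_log(outdir, log)
    return outdir


def _write_log(outdir, log, failed=None, error=None):
    payload = {"stages": log}
    if failed:
        payload["failed_stage"] = failed
        payload["error"] = error
    (Path(outdir) / "run_log.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, state, outdir, prov):
    sim_cfg = cfg.get("simulate", {})
    ds = simulate.simulate_heb25(
        seed=stage_seed(cfg["seed"], "simulate"),
        n_markers=int(sim_cfg.get("n_markers", 2000)))
    state["dataset"] = ds
    io.write_genotypes(ds.genotypes, outdir / "genotypes.tsv", **prov)
    io.write_map(ds.gmap, outdir / "map.tsv", **prov)
    io.write_tsv(ds.phenotypes, outdir / "phenotypes.tsv", **prov)
    io.write_series(ds.families, outdir / "families.tsv", **prov)
    io.write_series(ds.haplotypes, outdir / "haplotypes.tsv", **prov)
    truth = ds.truth["qtl"].copy()
    truth["seg_families"] = truth["seg_families"].map(lambda t: ",".join(t))
    io.write_tsv(truth, outdir / "truth_qtl.tsv", **prov)
    io.write_tsv(ds.truth["polygenic_effects"], outdir / "truth_polygenic.tsv", **prov)
    return len(ds.genotypes)


def _stage_qc(cfg, state, outdir, prov):
    """Exercise the QC chain on chip-style calls re-exported from the
    simulated population: filter, IBS-encode, impute, parent LD and PCA."""
    from . import qc
    ds = _require_dataset(cfg, state)
    if ds.population is None:
        raise ConfigError("the qc stage needs a simulated population (run simulate)")
    qcfg = cfg.get("qc", {})
    raw, parents = simulate.to_raw_calls(
        ds.population, missing_rate=float(qcfg.get("missing_rate", 0.02)),
        seed=stage_seed(cfg["seed"], "qc"))
    filt, report = qc.filter_snps(raw, float(qcfg.get("max_missing_fraction", 0.10)))
    enc = qc.encode_ibs(filt, parents[filt.columns], ds.families)
    imp = qc.impute_mni(enc, ds.families)
    io.write_tsv(report.disposition.rename_axis("marker").reset_index(),
                 outdir / "filter_report.tsv", **prov)
    io.write_genotypes(imp, outdir / "qc_genotypes.tsv", **prov)
    # parent-panel diversity diagnostics
    pan = ds.population.panel
    pdos = pd.DataFrame(
        np.vstack([pan.recurrent * 0, pan.donors * 2]),
        index=parents.index, columns=ds.genotypes.columns).astype(float)
    ld = qc.ld_r2(pdos, ds.gmap, max_pairs=int(qcfg.get("max_ld_pairs", 20000)),
                  seed=stage_seed(cfg["seed"], "qc"))
    io.write_tsv(ld, outdir / "ld_pairs.tsv", **prov)
    pscore, qscore, ratio = qc.pca_parents_project(pdos, imp)
    io.write_tsv(pscore.rename_axis("parent").reset_index(),
                 outdir / "pca_parents.tsv", **prov)
    io.write_tsv(pd.DataFrame({"component": ["PC1", "PC2"],
                               "variance_fraction": ratio[:2]}),
                 outdir / "pca_variance.tsv", **prov)
    return int(report.n_kept)


def _require_dataset(cfg, state):
    if "dataset" in state:
        return state["dataset"]
    inputs = cfg.get("inputs", {})
    needed = ["genotypes", "map", "phenotypes", "families"]
    missing = [k for k in needed if k not in inputs]
    if missing:
        raise ConfigError(f"no simulate stage and missing inputs: {missing}")
    geno = io.read_genotypes(inputs["genotypes"])
    gmap = io.read_map(inputs["map"])
    pheno = io.read_tsv(inputs["phenotypes"])
    fam = io.read_series(inputs["families"], "family")
    hap = (io.read_series(inputs["haplotypes"], "haplotype")
           if "haplotypes" in inputs else pd.Series(pd.NA, index=geno.index))
    ds = simulate.NAMDataset(geno, gmap, fam, hap, pheno, {}, None, None)
    state["dataset"] = ds
    return ds


def _stage_phenostats(cfg, state, outdir, prov):
    ds = _require_dataset(cfg, state)
    res = MultiEnvTrial(ds.phenotypes).fit()
    state["trial"] = res
    vc = res.variance_components
    io.write_tsv(pd.DataFrame({
        "component": ["sigma2_G", "sigma2_E", "sigma2_GE", "sigma2_R", "h2"],
        "value": [vc.sigma2_G, vc.sigma2_E, vc.sigma2_GE, vc.sigma2_R,
                  res.heritability()]}), outdir / "variance_components.tsv", **prov)
    io.write_series(res.blues, outdir / "blues.tsv", **prov)
    return len(res.blues)


def _model_b(cfg, state):
    if "modelb" in state:
        return state["modelb"]
    ds = state["dataset"]
    res = state["trial"]
    model = ModelB(res.blues, ds.genotypes, ds.families, ds.gmap)
    state["modelb"] = model
    return model


def _stage_gwas(cfg, state, outdir, prov):
    gcfg = cfg.get("gwas", {})
    model = _model_b(cfg, state)
    res = model.fit(alpha=float(gcfg.get("alpha", 0.05)),
                    exclusion_cm=float(gcfg.get("exclusion_cm", 1.0)),
                    max_cofactors=int(gcfg.get("max_cofactors", 50)),
                    family_effects=True)
    state["gwas"] = res
    tab = res.table.copy()
    io.write_tsv(tab, outdir / "association.tsv", **prov)
    io.write_tsv(res.family_effects.reset_index(), outdir / "family_effects.tsv", **prov)
    io.write_tsv(res.qtl_table(float(gcfg.get("group_cm", 5.0))),
                 outdir / "qtl.tsv", **prov)
    return len(tab)


def _stage_epistasis(cfg, state, outdir, prov):
    ecfg = cfg.get("epistasis", {})
    model = _model_b(cfg, state)
    gwas_res = state.get("gwas")
    sig = list(gwas_res.significant["marker"]) if gwas_res is not None else []
    pairs = grid_pairs(state["dataset"].gmap, sig,
                       grid_cm=float(ecfg.get("grid_cm", 5.0)))
    max_pairs = int(ecfg.get("max_pairs", 5000))
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(stage_seed(cfg["seed"], "epistasis"))
        keep = rng.choice(len(pairs), max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    res = model.fit_epistasis(pairs, cofactors=gwas_res.cofactors if gwas_res else None)
    io.write_tsv(res.table, outdir / "interactions.tsv", **prov)
    return len(res.table)


def _stage_haplo(cfg, state, outdir, prov):
    ds = state["dataset"]
    if ds.haplotypes.isna().all():
        raise ConfigError("no haplotype assignments available")
    model = _model_b(cfg, state)
    anchor = cfg.get("haplo", {}).get("anchor_marker")
    if anchor is None:
        if ds.arch is None or ds.arch.haplotype_locus is None:
            raise ConfigError("haplo stage needs an anchor_marker")
        anchor = ds.arch.haplotype_locus.marker
    res = model.fit_haplotypes(ds.haplotypes, anchor,
                               reference=simulate.RECURRENT_HAPLOTYPE)
    state["haplo"] = res
    io.write_tsv(pd.DataFrame({"haplotype": res.adjusted_means.index,
                               "adjusted_mean": res.adjusted_means.to_numpy(),
                               "n_lines": res.counts.to_numpy()}),
                 outdir / "haplotype_means.tsv", **prov)
    io.write_tsv(res.comparisons, outdir / "haplotype_comparisons.tsv", **prov)
    return len(res.comparisons)


def _stage_predict(cfg, state, outdir, prov):
    from .prediction import RRBLUP, BayesCPi
    ds = state["dataset"]
    res = state["trial"]
    vc = res.variance_components
    y = res.blues
    pcfg = cfg.get("predict", {})
    rr = RRBLUP(y, ds.genotypes, vc.sigma2_G, vc.sigma2_R,
                state["trial"].model.n_environments).fit()
    out = pd.DataFrame({"marker": rr.effects.index, "rrblup_effect": rr.effects.to_numpy()})
    if pcfg.get("bayescpi", False):
        bc = BayesCPi(y, ds.genotypes, vc.sigma2_G, vc.sigma2_R,
                      state["trial"].model.n_environments).fit(
            cycles=int(pcfg.get("cycles", 10000)),
            burnin=int(pcfg.get("burnin", 1000)),
            seed=stage_seed(cfg["seed"], "predict"))
        out["bayescpi_effect"] = bc.effects.to_numpy()
        out["inclusion_prob"] = bc.inclusion_prob.to_numpy()
    io.write_tsv(out, outdir / "marker_effects.tsv", **prov)
    meta = {"lambda": rr.lambda_, "sigma2_G": vc.sigma2_G, "sigma2_R": vc.sigma2_R}
    (outdir / "prediction_meta.txt").write_text(
        "\n".join(f"{k}\t{v}" for k, v in meta.items()) + "\n")
    return len(out)


def _stage_cv(cfg, state, outdir, prov):
    ds = state["dataset"]
    trial = state["trial"]
    vc = trial.variance_components
    ccfg = cfg.get("cv", {})
    runs = int(ccfg.get("runs", 100))
    gwas_res = state.get("gwas") or _model_b(cfg, state).fit()
    peaks_tab = gwas_res.qtl_table().sort_values("p_holm")
    peaks = list(peaks_tab["peak_marker"])
    if not peaks:
        raise ConfigError("no QTL peaks available for the CV model ladder")
    ladder = crossval.model_ladder(
        trial.blues, ds.genotypes, ds.families, trial.heritability(),
        vc.sigma2_G, vc.sigma2_R, trial.model.n_environments, ds.gmap, peaks,
        runs=runs, seed=stage_seed(cfg["seed"], "cv"),
        bayes_cycles=int(ccfg.get("bayes_cycles", 10000)),
        bayes_burnin=int(ccfg.get("bayes_burnin", 1000)))
    io.write_tsv(ladder, outdir / "cv_summary.tsv", **prov)
    detect = crossval.cv_evaluate(
        crossval.GWASPeakRunner(), trial.blues, ds.genotypes, ds.families,
        trial.heritability(), ds.gmap, runs=runs,
        seed=stage_seed(cfg["seed"], "cv"))
    io.write_tsv(detect.per_run, outdir / "cv_runs_gwas.tsv", **prov)
    io.write_tsv(detect.detection_counts.rename("detections").rename_axis("marker")
                 .reset_index(), outdir / "detection_counts.tsv", **prov)
    return runs


def _stage_report(cfg, state, outdir, prov):
    return len(summarize_run(outdir).splitlines())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "phenostats": _stage_phenostats,
    "gwas": _stage_gwas,
    "epistasis": _stage_epistasis,
    "haplo": _stage_haplo,
    "predict": _stage_predict,
    "cv": _stage_cv,
    "report": _stage_report,
}


def summarize_run(run_dir) -> str:
    """Assemble a text summary from a completed run directory: the QTL table
    and, when present, the CV model-comparison table. Missing stage outputs
    are listed by name."""
    run_dir = Path(run_dir)
    parts = [f"Run summary: {run_dir}"]
    missing = []
    qtl_path = run_dir / "qtl.tsv"
    if qtl_path.exists():
        qtl = io.read_tsv(qtl_path)
        parts.append("\nQTL summary")
        parts.append(qtl.to_string(index=False) if len(qtl) else "(no significant QTL)")
    else:
        missing.append("qtl.tsv")
    cv_path = run_dir / "cv_summary.tsv"
    if cv_path.exists():
        cv = io.read_tsv(cv_path)
        parts.append("\nModel comparison (mean cross-validated p_G)")
        parts.append(cv.to_string(index=False))
    else:
        missing.append("cv_summary.tsv")
    if missing:
        parts.append("\nmissing stage outputs: " + ", ".join(missing))
    text = "\n".join(parts) + "\n"
    (run_dir / "summary.txt").write_text(text)
    return text
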