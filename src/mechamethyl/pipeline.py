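"""End-to-end orchestration: simulate (or load) -> QC -> per-model DM ->
meta-analysis -> DMR scan -> chromatin enrichment -> tCpG integration ->
optional clinical stage, driven by a single config mapping and producing a
machine-readable run summary."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as syn
from .errors import ConfigError
from .qc_normalization import MethylationDataset, run_qc
from .differential_methylation import dm_analysis
from .meta_analysis import meta_ewas
from .dmr_scanner import scan_dmrs, dmr_significance, dmrs_to_frame
from .chromatin_enrichment import enrichment_by_state
from .expression_integration import (
    differential_expression,
    map_cpgs_to_genes,
    overlap_tcpg_sets,
    prioritize_tcpgs,
    region_category_summary,
)
from .clinical_and_qpcr import correlate_with_severity

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scale": "beta",
    "thresholds": {
        "dm_fdr": 0.01,
        "expr_fdr": 0.05,
        "detection_p": 0.01,
        "dmr": {"min_dm": 3, "max_gap_bp": 1000, "max_nondm": 3},
    },
    "simulation": {
        "design": {},   # StudyDesign field overrides
        "effects": {},  # EffectSpec field overrides
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    th = cfg["thresholds"]
    for key in ("dm_fdr", "expr_fdr", "detection_p"):
        if not 0 < th[key] < 1:
            raise ConfigError(f"threshold {key}={th[key]} must lie in (0, 1)")
    dmr = th["dmr"]
    if dmr["min_dm"] < 1 or dmr["max_gap_bp"] < 1 or dmr["max_nondm"] < 0:
        raise ConfigError("invalid DMR parameters")
    if cfg["scale"] not in ("beta", "m"):
        raise ConfigError("scale must be 'beta' or 'm'")
    if "simulation" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulation' block or an 'inputs' block")
    return cfg


def _load_inputs(paths: dict) -> tuple[dict, pd.DataFrame, syn.CountMatrix | None]:
    annotation = pd.read_csv(paths["annotation"], sep="\t", index_col=0).fillna({"genes": "", "categories": ""})
    samples = pd.read_csv(paths["samples"], index_col=0)
    datasets = {}
    for model in syn.MODELS:
        beta = pd.read_csv(paths[f"beta_{model}"], sep="\t", index_col=0)
        detp = pd.read_csv(paths[f"detp_{model}"], sep="\t", index_col=0)
        sub = samples[samples["model"] == model]
        datasets[model] = MethylationDataset(
            beta=beta[sub.index], detp=detp[sub.index], samples=sub, model_label=model
        )
    counts = None
    if "counts" in paths:
        counts = syn.CountMatrix(
            counts=pd.read_csv(paths["counts"], sep="\t", index_col=0), samples=samples
        )
    return datasets, annotation, counts


def run_pipeline(config: dict | None = None, out_dir: "str | Path | None" = None) -> dict:
    """Run the full analysis chain and return the run summary dict.

    With an ``out_dir`` every stage output is written (TSV/CSV/JSON) along
    with ``run_summary.json``.  Identical config + seed give identical
    summaries.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    truth = None
    if "inputs" in cfg:
        datasets, annotation, counts = _load_inputs(cfg["inputs"])
    else:
        sim = cfg["simulation"]
        design = syn.StudyDesign(**{**sim.get("design", {}), "seed": seed})
        effects = syn.EffectSpec(**sim.get("effects", {}))
        annotation = syn.generate_probe_annotation(design)
        datasets, truth = syn.generate_methylation_experiment(design, effects, annotation)
        counts = syn.generate_expression_counts(design, effects, annotation, truth)
        if out is not None:
            annotation.to_csv(out / "annotation.tsv", sep="\t")
            counts.counts.to_csv(out / "counts.tsv", sep="\t")
            pd.concat([d.samples for d in datasets.values()]).to_csv(out / "samples.csv")
            for model, ds in datasets.items():
                ds.beta.to_csv(out / f"beta_{model}.tsv", sep="\t")
                ds.detp.to_csv(out / f"detp_{model}.tsv", sep="\t")
            (out / "truth.json").write_text(truth.to_json())

    summary: dict = {"config": cfg, "stages": {}}

    # ---- QC + per-model differential methylation -------------------------
    dm_tables = {}
    qc_reports = {}
    for model, ds in datasets.items():
        ds_qc, report = run_qc(ds, detection_p=th["detection_p"], blacklist=cfg.get("blacklist"))
        qc_reports[model] = report
        dm = dm_analysis(ds_qc, scale=cfg["scale"])
        dm_tables[model] = dm
        if out is not None:
            dm.to_csv(out / f"dm_{model}.tsv", sep="\t")
            (out / f"qc_{model}.json").write_text(json.dumps(report.to_dict(), indent=2))
    summary["stages"]["qc"] = {m: r.to_dict() for m, r in qc_reports.items()}

    # ---- meta-analysis ----------------------------------------------------
    meta = meta_ewas(*(dm_tables[m] for m in syn.MODELS), fdr_threshold=th["dm_fdr"])
    n_dm = int(meta["dm_flag"].sum())
    summary["stages"]["meta"] = {"n_probes": len(meta), "n_dm_cpgs": n_dm}
    if out is not None:
        meta.to_csv(out / "meta.tsv", sep="\t")

    # ---- DMR scan ---------------------------------------------------------
    dmrs = scan_dmrs(
        meta, annotation,
        min_dm=th["dmr"]["min_dm"],
        max_gap_bp=th["dmr"]["max_gap_bp"],
        max_nondm=th["dmr"]["max_nondm"],
    )
    dmrs = dmr_significance(dmrs, meta)
    summary["stages"]["dmr"] = {"n_dmrs": len(dmrs)}
    if out is not None:
        dmrs_to_frame(dmrs).to_csv(out / "dmr.bed", sep="\t", index=False)
        (out / "dmr_members.json").write_text(
            json.dumps({f"{d.chrom}:{d.start}-{d.end}": d.probe_ids for d in dmrs}, indent=2)
        )

    # ---- chromatin-state enrichment --------------------------------------
    enr = enrichment_by_state(meta, annotation)
    summary["stages"]["enrichment"] = {
        "n_states_tested": int(enr["p"].notna().sum()),
        "n_significant": int((enr["q"] < 0.05).sum()),
    }
    if out is not None:
        enr.to_csv(out / "enrichment.tsv", sep="\t")

    # ---- expression integration ------------------------------------------
    tcpg_summary = {}
    tcpgs = pd.DataFrame()
    if counts is not None:
        pairs = map_cpgs_to_genes(meta, annotation)
        de = differential_expression(counts)
        tcpgs = prioritize_tcpgs(pairs, de, expr_fdr=th["expr_fdr"])
        tcpg_summary = {
            "n_cpg_gene_pairs": len(pairs),
            "n_mapped_cpgs": int(pairs["probe_id"].nunique()) if not pairs.empty else 0,
            "n_tcpg_pairs": len(tcpgs),
            "n_tcpg_genes": int(tcpgs["gene"].nunique()) if not tcpgs.empty else 0,
            "category_proportions": region_category_summary(tcpgs),
        }
        if cfg.get("external_tcpg"):
            ext = pd.read_csv(cfg["external_tcpg"])
            tcpg_summary["overlap"] = overlap_tcpg_sets(tcpgs, ext)
        if out is not None:
            tcpgs.to_csv(out / "tcpg.tsv", sep="\t", index=False)
            de.to_csv(out / "de.tsv", sep="\t")
    summary["stages"]["tcpg"] = tcpg_summary

    # ---- recovery scoring against the planted truth ----------------------
    if truth is not None:
        called = set(meta.index[meta["dm_flag"]])
        truth_dm = set(truth.dm_probes)
        tp = len(called & truth_dm)
        dmr_hits = sum(
            any(d.overlaps(chrom, start, end) for d in dmrs)
            for chrom, start, end in truth.planted_dmrs
        )
        called_genes = (
            {str(g).upper() for g in tcpgs["gene"]} if not tcpgs.empty else set()
        )
        linked = {g.upper() for g in truth.linked_genes}
        union = called_genes | linked
        summary["recovery"] = {
            "dm_sensitivity": tp / max(1, len(truth_dm)),
            "dm_fdp": (len(called) - tp) / max(1, len(called)),
            "n_planted_dmrs": len(truth.planted_dmrs),
            "dmr_recovery": dmr_hits / max(1, len(truth.planted_dmrs)),
            "tcpg_gene_jaccard": len(called_genes & linked) / max(1, len(union)),
        }

    # ---- clinical stage (simulated cohort on selected CpGs) ---------------
    if "clinical" in cfg:
        ccfg = cfg["clinical"]
        cpgs = list(ccfg.get("cpgs", [])) or list(meta.index[meta["dm_flag"]][:2])
        slopes = {c: float(ccfg.get("slope", -0.1)) for c in cpgs}
        cohort = syn.generate_clinical_cohort(
            int(ccfg.get("n_patients", 500)), cpgs, slopes, seed=seed + 101
        )
        clin = {}
        for c in cpgs:
            slope, se, p = correlate_with_severity(cohort, c, scale=ccfg.get("scale", "beta"))
            clin[c] = {"slope": slope, "se": se, "p": p}
        summary["stages"]["clinical"] = clin
        if out is not None:
            cohort.to_csv(out / "clinical.csv")

    if out is not None:
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
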