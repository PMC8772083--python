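"""End-to-end pipeline: simulate -> call -> compare -> fragsize -> signatures -> cna.

A single YAML config drives every stage; all randomness flows from one
master seed, so two runs with the same config produce byte-identical
outputs. Timestamps appear only in logs, never in result files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import cna, compare, fragments, signatures, simulate, somatic, vcfio

log = logging.getLogger("cfplasma")

_SIM_KEYS = {f.name for f in dataclasses.fields(simulate.SimConfig)} - {"gene_models"}
_SOMATIC_KEYS = {f.name for f in dataclasses.fields(somatic.SomaticParams)}

_DEFAULTS = {
    "seed": 0,
    "log_level": "INFO",
    "simulate": {},
    "somatic": {},
    "compare": {"callable_mb": compare.DEFAULT_CALLABLE_MB},
    "fragsize": {"window_lo": 300, "window_hi": 350, "multi_variant": "per_variant"},
    "signatures": {"k": 2, "n_runs": 20, "reference_signatures": None},
    # default bin width suits the synthetic megabase-scale genome; use
    # 1_000_000 for real whole-genome fragment tables
    "cna": {"bin_width": 10_000, "z_threshold": 3.0, "min_bins": 3,
            "min_mapq": cna.DEFAULT_MIN_MAPQ},
}


class ConfigError(ValueError):
    pass


def validate_config(path_or_dict) -> dict:
    """Load, default-fill and strictly validate a pipeline config.

    Unknown keys anywhere are rejected by name; an empty file yields the
    full-defaults config.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    cfg = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            block = dict(raw.get(key) or {})
            allowed = set(default)
            if key == "simulate":
                allowed = _SIM_KEYS
            elif key == "somatic":
                allowed = _SOMATIC_KEYS
            bad = set(block) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in '{key}' block: {sorted(bad)}")
            cfg[key] = {**default, **block}
        else:
            cfg[key] = raw.get(key, default)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def _sim_config(cfg: dict) -> simulate.SimConfig:
    block = dict(cfg["simulate"])
    block.setdefault("seed", cfg["seed"])
    if "background_fragment_model" in block:
        block["background_fragment_model"] = simulate.FragmentLengthModel(
            **block["background_fragment_model"])
    if "tumour_fragment_model" in block:
        block["tumour_fragment_model"] = simulate.FragmentLengthModel(
            **block["tumour_fragment_model"])
    for key in ("tumour_signature", "background_signature"):
        if key in block:
            block[key] = np.asarray(block[key], dtype=float)
    if "background_vaf_range" in block:
        block["background_vaf_range"] = tuple(block["background_vaf_range"])
    return simulate.SimConfig(**block)


def _site_id(site) -> str:
    return f"{site[0]}_{site[1]}_{site[2]}_{site[3]}"


def run_all(config: dict | str | Path, out_dir) -> dict:
    """Run every stage in dependency order; returns the aggregated report.

    A stage failure halts downstream stages; the report written so far and
    the cause are preserved in ``report.json``.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), 20))
    with open(out / "config.used.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    report: dict = {"seed": cfg["seed"]}
    try:
        _run_stages(cfg, out, report)
    except Exception as exc:  # record the cause, halt downstream stages
        report["failed"] = {"stage": report.get("_stage"), "error": str(exc)}
        _write_report(report, out)
        raise
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    report.pop("_stage", None)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_stages(cfg: dict, out: Path, report: dict) -> None:
    # --- simulate
    report["_stage"] = "simulate"
    sim_cfg = _sim_config(cfg)
    study = simulate.simulate_study(sim_cfg)
    contigs = sim_cfg.chromosome_lengths()
    simulate.write_fasta(study.reference, out / "reference.fa")
    simulate.write_gene_models(study.gene_models, out / "gene_models.tsv")
    for name, pileup in study.pileups.items():
        simulate.write_pileup(pileup, out / f"pileup_{name}.tsv")
    simulate.write_fragments(study.plasma_fragments, out / "fragments_plasma.tsv")
    simulate.write_fragments(study.germline_fragments, out / "fragments_germline.tsv")
    simulate.write_truth(study.truth, out / "truth.vcf", out / "truth.tsv", contigs)
    report["simulate"] = {
        "n_germline": len(study.truth.germline),
        "n_tumour_mutations": len(study.truth.tumour),
        "n_background_mutations": len(study.truth.background),
        "n_plasma_fragments": int(study.plasma_fragments["fragment_id"].nunique()),
    }
    log.info("simulated study: %s", report["simulate"])

    # --- somatic calling (plasma vs germline, tumour vs germline)
    report["_stage"] = "call"
    params = somatic.SomaticParams(**cfg["somatic"])
    calls = {}
    stage_counts = {}
    for case_name in ("plasma", "tumour"):
        cs, counts = somatic.run_somatic_pipeline(
            study.pileups["germline"], study.pileups[case_name], params)
        finals = somatic.final_calls(cs)
        vcfio.write_calls_vcf(finals, out / f"somatic_{case_name}.vcf", contigs,
                              "GERMLINE", case_name.upper())
        calls[case_name] = finals
        stage_counts[case_name] = counts
    report["call"] = stage_counts

    # --- compare
    report["_stage"] = "compare"
    paired = compare.classify_shared(calls["plasma"], calls["tumour"], "SIM")
    ann = {
        f"SIM_{tag}": [compare.annotate(s, study.gene_models, study.reference)
                       for s in sites]
        for tag, sites in (("P0", sorted(paired.plasma)), ("T0", sorted(paired.tumour)))
    }
    table = compare.summarize_cohort(
        {"SIM_P0": paired.plasma, "SIM_T0": paired.tumour},
        {"SIM": paired}, ann, cfg["compare"]["callable_mb"])
    table.to_csv(out / "summary_table.tsv", sep="\t", index=False)
    report["compare"] = {
        "n_plasma": len(paired.plasma), "n_tumour": len(paired.tumour),
        "n_shared": len(paired.shared),
        "pct_shared_plasma": round(paired.pct_shared_plasma, 1),
        "pct_shared_tumour": round(paired.pct_shared_tumour, 1),
    }

    # --- fragment size
    report["_stage"] = "fragsize"
    shared_ids = {_site_id(s) for s in paired.shared}
    unique_ids = {_site_id(s) for s in paired.unique_plasma}
    truth_ids = {v.variant_id for v in study.truth.all_variants()}
    labelled = fragments.extract_somatic_fragments(
        study.plasma_fragments, shared_ids, unique_ids, known_ids=truth_ids)
    profile = fragments.length_profile(labelled, cfg["fragsize"]["multi_variant"])
    profile.counts.to_csv(out / "fragment_length_counts.tsv", sep="\t")
    profile.cdf().round(6).to_csv(out / "fragment_length_cdf.tsv", sep="\t")
    fragments.enrichment_curve(profile).to_csv(
        out / "fragment_enrichment_curve.tsv", sep="\t", index=False)
    lo, hi = cfg["fragsize"]["window_lo"], cfg["fragsize"]["window_hi"]
    window, overall = fragments.window_shared_fraction(profile, lo, hi)
    report["fragsize"] = {
        "modal_length_all": profile.mode("all"),
        "window_lo": lo, "window_hi": hi,
        "window_shared_fraction": None if window is None else round(window, 4),
        "overall_shared_fraction": None if overall is None else round(overall, 4),
    }

    # --- signatures
    report["_stage"] = "signatures"
    sig_cfg = cfg["signatures"]
    refs = (signatures.read_reference_signatures(sig_cfg["reference_signatures"])
            if sig_cfg["reference_signatures"]
            else signatures.default_reference_signatures())
    subsets = {
        "plasma_all": sorted(paired.plasma),
        "plasma_shared": sorted(paired.shared),
        "plasma_unique": sorted(paired.unique_plasma),
        "tumour_all": sorted(paired.tumour),
    }
    catalog = signatures.catalog_from_variants(
        {k: v for k, v in subsets.items() if v}, study.reference)
    catalog.to_csv(out / "mutation_catalog.tsv", sep="\t")
    contrib = {}
    for col in catalog.columns:
        rel = signatures.relative(signatures.refit(catalog[col], refs))
        contrib[col] = rel.round(4).to_dict()
    report["signatures"] = {"refit_relative_contributions": contrib}
    denovo_cols = [c for c in ("plasma_all", "tumour_all") if c in catalog.columns]
    if len(denovo_cols) >= 1 and int(sig_cfg["k"]) < 10:
        sig_set = signatures.extract_denovo(catalog[denovo_cols], int(sig_cfg["k"]),
                                            int(sig_cfg["n_runs"]), cfg["seed"])
        sig_set.signatures.round(6).to_csv(out / "denovo_signatures.tsv", sep="\t")
        sig_set.contributions.round(4).to_csv(out / "denovo_contributions.tsv", sep="\t")
        report["signatures"]["denovo_reconstruction_error"] = round(
            sig_set.reconstruction_error, 4)

    # --- CNA screen
    report["_stage"] = "cna"
    cna_cfg = cfg["cna"]
    case_bins = cna.bin_counts(study.plasma_fragments, contigs,
                               cna_cfg["bin_width"], cna_cfg["min_mapq"])
    normal_bins = cna.bin_counts(study.germline_fragments, contigs,
                                 cna_cfg["bin_width"], cna_cfg["min_mapq"])
    ratios = cna.log_ratio(case_bins, normal_bins)
    ratios.round(6).to_csv(out / "cna_log_ratios.tsv", sep="\t", index=False)
    segments = cna.segment_and_call(ratios, cna_cfg["z_threshold"],
                                    cna_cfg["min_bins"])
    cna.segments_frame(segments).to_csv(out / "cna_segments.tsv", sep="\t", index=False)
    report["cna"] = {
        "n_segments": len(segments),
        "tumour_fraction_estimate": round(cna.estimate_tumour_fraction(segments), 4),
    }
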