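"""End-to-end pipeline orchestration.

Runs the stages — repeat parsing and merging, transcript/locus
construction, RTE-usage classification, differential expression,
discordance, subgroup enrichment, isoform-balance stratification and
survival — from a structured config, writing a results bundle with a
manifest sufficient to re-run identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import stratify, write_strata_table
from .discordance import (
    cross_cancer_sharing,
    find_discordant,
    write_discordance_report,
    write_sharing_matrix,
)
from .enrichment import rte_subgroup_enrichment, write_enrichment_table
from .expression import (
    QuantMatrix,
    differential_transcripts,
    read_quant,
    read_sample_meta,
    write_de_table,
)
from .intervals import ValidationError
from .repeats import assign_subgroup, merge_elements, parse_repeatmasker, write_bed6
from .simulate import SyntheticConfig, generate
from .survival import (
    cox_ph,
    kaplan_meier_by_group,
    logrank,
    write_cox_table,
    write_km_table,
)
from .transcripts import build_loci, classify_rte_usage, index_elements, read_gtf, write_locus_map

log = logging.getLogger("rteshift")

DEFAULT_THRESHOLDS = {
    "fc": 1.5,
    "alpha": 0.05,
    "alpha_q": 0.05,
    "pseudocount": 0.01,
    "min_overlap": 10,
    "max_gap": 100,
}


def validate_config(config: dict) -> dict:
    """Validate and normalise a run config; raises ValidationError."""
    cfg = dict(config)
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs either 'synthetic' or 'inputs'")
    if "inputs" in cfg:
        for key in ("quant", "gtf", "rmsk", "metadata"):
            if key not in cfg["inputs"]:
                raise ValidationError(f"inputs missing {key!r}")
    comparisons = cfg.get("comparisons", [])
    if not comparisons:
        raise ValidationError("config must define at least one comparison")
    for comp in comparisons:
        for key in ("name", "group_a", "group_b"):
            if key not in comp:
                raise ValidationError(f"comparison missing {key!r}")
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key, v in thresholds.items():
        if not (isinstance(v, (int, float)) and v > 0):
            raise ValidationError(f"threshold {key} must be positive, got {v!r}")
    cfg["thresholds"] = thresholds
    cfg.setdefault("stratification", {"rule": "fixed_tpm", "param": 1.0})
    cfg.setdefault("locus_mode", "by_overlap")
    return cfg


def _select_samples(meta: pd.DataFrame, selector: dict) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for col, value in selector.items():
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks column {col!r}")
        mask &= meta[col] == value
    return list(meta.index[mask])


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the pipeline; returns a results dict and writes the bundle."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    thresholds = cfg["thresholds"]
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        timings[name] = _time.monotonic()
        return name

    def done(name):
        timings[name] = _time.monotonic() - timings[name]
        log.info("stage %s done in %.2fs", name, timings[name])

    truth = None
    s = stage("inputs")
    if "synthetic" in cfg:
        syn = SyntheticConfig(**{**cfg["synthetic"], "seed": seed})
        paths, truth = generate(syn, outdir / "synthetic")
    else:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        for key, p in paths.items():
            if not p.exists():
                raise ValidationError(f"missing input {key}: {p}")
    done(s)

    s = stage("repeats")
    features = parse_repeatmasker(paths["rmsk"])
    elements = merge_elements(features, max_gap=int(thresholds["max_gap"]))
    write_bed6(elements, outdir / "merged_elements.bed")
    done(s)

    s = stage("transcripts")
    transcripts = read_gtf(paths["gtf"])
    loci, tx2locus = build_loci(transcripts, mode=cfg["locus_mode"])
    write_locus_map(tx2locus, outdir / "locus_map.tsv")
    trees = index_elements(elements)
    locus_strand = {l.locus_id: l.strand for l in loci}
    tx_subgroups: dict[str, set[str]] = {}
    rte_transcripts: set[str] = set()
    for t in transcripts:
        hs = locus_strand.get(tx2locus[t.transcript_id])
        usages = classify_rte_usage(
            t, trees, min_overlap=int(thresholds["min_overlap"]),
            host_strand=hs if hs in ("+", "-") else None,
        )
        if usages:
            rte_transcripts.add(t.transcript_id)
            for u in usages:
                sg = assign_subgroup(
                    u.element.members[0].family
                    if not u.element.is_provirus
                    else u.element.name,
                    u.element.members[0].repeat_class,
                )
                tx_subgroups.setdefault(t.transcript_id, set()).add(sg)
    done(s)

    s = stage("expression")
    qm = read_quant(paths["quant"])
    meta = read_sample_meta(paths["metadata"])
    done(s)

    s = stage("differential")
    disc_results = []
    for comp in cfg["comparisons"]:
        name = comp["name"]
        group_a = _select_samples(meta, comp["group_a"])
        group_b = _select_samples(meta, comp["group_b"])
        de = differential_transcripts(
            qm,
            group_a,
            group_b,
            pseudocount=thresholds["pseudocount"],
            fc_threshold=thresholds["fc"],
            alpha=thresholds["alpha"],
            alpha_q=thresholds["alpha_q"],
        )
        write_de_table(de, outdir / f"de_{name}.tsv")
        disc = find_discordant(de, tx2locus, cancer_type=name)
        write_discordance_report(disc, outdir / f"discordance_{name}.tsv")
        disc_results.append(disc)
        results[name] = {
            "n_de": disc.n_de,
            "n_disc": disc.n_disc,
            "discordant_loci": sorted(disc.discordant_loci),
            "discordant_fraction": disc.discordant_fraction,
        }

        enr = rte_subgroup_enrichment(
            disc.discordant_transcripts, set(qm.transcript_ids), tx_subgroups
        )
        write_enrichment_table(enr, outdir / f"enrichment_{name}.tsv")
        results[name]["enrichment"] = {
            r.subgroup: {"fold": r.fold_enrichment, "p_holm": r.p_holm} for r in enr
        }
    done(s)

    if len(disc_results) >= 2:
        s = stage("sharing")
        sharing = cross_cancer_sharing(disc_results)
        write_sharing_matrix(sharing, outdir / "sharing.tsv")
        results["sharing"] = sharing
        done(s)

    s = stage("survival")
    surv_meta = meta.dropna(subset=[c for c in ("os_time", "os_event") if c in meta.columns])
    if {"os_time", "os_event"} <= set(meta.columns) and len(surv_meta) >= 4:
        # per-sample RTE activity score: total TPM of RTE-overlapping
        # transcripts in discordant loci of the first comparison
        disc_loci = disc_results[0].discordant_loci
        score_tx = [
            t for t in rte_transcripts
            if tx2locus.get(t) in disc_loci and t in qm.tpm.index
        ]
        if score_tx:
            score = qm.tpm.loc[score_tx, list(surv_meta.index)].sum(axis=0)
        else:
            score = qm.tpm[list(surv_meta.index)].sum(axis=0)
        rule = cfg["stratification"]
        strat = stratify(score, rule=rule.get("rule", "fixed_tpm"), param=rule.get("param", 1.0))
        write_strata_table(strat, outdir / "strata.tsv")
        time_v = surv_meta["os_time"].to_numpy(dtype=float)
        event_v = surv_meta["os_event"].to_numpy(dtype=int)
        groups = strat.labels.loc[surv_meta.index].to_numpy()
        results["survival"] = {"strata_counts": strat.counts}
        km = kaplan_meier_by_group(time_v, event_v, groups)
        write_km_table(km, outdir / "km.tsv")
        if len(set(groups)) == 2:
            chi2, p = logrank(time_v, event_v, groups)
            covs = pd.DataFrame({"rte_high": (groups == "high").astype(float)},
                                index=surv_meta.index)
            if "stage" in surv_meta.columns and surv_meta["stage"].nunique() > 1:
                dummies = pd.get_dummies(surv_meta["stage"], prefix="stage").iloc[:, 1:]
                covs = pd.concat([covs, dummies.astype(float)], axis=1)
            fit = cox_ph(covs, time_v, event_v)
            write_cox_table(fit, outdir / "cox.tsv")
            results["survival"].update(
                {
                    "logrank_chi2": chi2,
                    "logrank_p": p,
                    "cox_hr_rte_high": fit["rte_high"].hr,
                    "cox_ci95": [fit["rte_high"].ci95_low, fit["rte_high"].ci95_high],
                }
            )
    done(s)

    manifest = {
        "package": "rteshift",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, default=str) + "\n"
    )
    if truth is not None:
        results["_truth"] = truth
    return results
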