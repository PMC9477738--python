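"""Orchestration: run every analysis stage from one config, with a JSON report.

The pipeline runs simulate? -> annotate -> motifs -> stratify -> diffbind ->
coregulate -> report.  Each stage writes its outputs before the next starts;
a stage whose inputs are missing is skipped and flagged in the report; a
failing stage aborts the run with its name.  Every run echoes its config and
seed into the report so stochastic stages are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coregulation as cr
from . import io_formats as iof
from . import motif_architecture as ma
from . import occupancy_stats as os_
from . import peak_annotation as pa
from . import synthetic_data as sd

__all__ = ["default_config", "validate_config", "load_config", "run_all", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def default_config() -> dict:
    """The shipped default: simulate-first run with the standard thresholds."""
    return {
        "seed": 0,
        "simulate": {},  # SimConfig defaults
        "annotation": {
            "upstream_window": 3000,
            "downstream_window": 1000,
            "anchor": "center",
            "bins": 50,
            "n_sets": 1000,
        },
        "motifs": [
            {"name": "gbox", "consensus": "CACGTG"},
            {"name": "dof", "consensus": "AAAAG"},
        ],
        "thresholds": {"fdr": 0.05, "fold_change": 1.5, "padj": 0.05, "alpha": 0.05},
        "stratify": {"motif": "gbox", "max_group": 3},
        "background_promoter_window": 1000,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    merged = default_config()
    # shallow per-section merge so partial configs inherit defaults
    for key, val in cfg.items():
        if key in ("annotation", "thresholds", "stratify") and isinstance(val, dict):
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    if "simulate" not in cfg and "inputs" in cfg:
        merged.pop("simulate", None)
    return merged


def validate_config(config: Mapping[str, Any] | str | Path) -> list[str]:
    """Check every config invariant; returns all violations (empty = ok)."""
    if not isinstance(config, Mapping):
        try:
            config = load_config(config)
        except Exception as exc:  # unparseable file -> single parse error
            return [f"cannot parse config: {exc}"]
    v: list[str] = []
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        v.append("seed must be a non-negative integer")
    th = config.get("thresholds", {})
    fdr = th.get("fdr", 0.05)
    if not (0 < fdr <= 1):
        v.append("fdr must be in (0,1]")
    if not (0 < th.get("padj", 0.05) <= 1):
        v.append("padj must be in (0,1]")
    if th.get("fold_change", 1.5) <= 0:
        v.append("fold_change must be > 0")
    if not (0 < th.get("alpha", 0.05) < 1):
        v.append("alpha must be in (0,1)")
    ann = config.get("annotation", {})
    for key in ("upstream_window", "downstream_window"):
        if ann.get(key, 0) < 0:
            v.append(f"{key} must be >= 0")
    if ann.get("anchor", "center") not in ("center", "summit"):
        v.append("anchor must be center or summit")
    if ann.get("n_sets", 1000) < 1:
        v.append("n_sets must be >= 1")
    if ann.get("bins", 50) < 2:
        v.append("bins must be >= 2")
    for spec in config.get("motifs", []):
        try:
            ma.MotifSpec(spec.get("name", ""), spec.get("consensus", ""))
        except Exception as exc:
            v.append(f"bad motif spec {spec}: {exc}")
    if "simulate" in config:
        try:
            sd.SimConfig(**{**config["simulate"], "seed": max(seed, 0)})
        except (TypeError, ValueError) as exc:
            v.append(f"bad simulate section: {exc}")
    else:
        inputs = config.get("inputs", {})
        if not inputs:
            v.append("config needs either a 'simulate' or an 'inputs' section")
        for key in ("genome", "genes", "peaks"):
            path = inputs.get(key)
            if path is None:
                v.append(f"inputs.{key} is required")
            elif not Path(path).exists():
                v.append(f"inputs.{key}: file not found: {path}")
        for key in ("counts", "pif4_targets"):
            path = inputs.get(key)
            if path is not None and not Path(path).exists():
                v.append(f"inputs.{key}: file not found: {path}")
        for gt, path in (inputs.get("deg_tables") or {}).items():
            if not Path(path).exists():
                v.append(f"inputs.deg_tables.{gt}: file not found: {path}")
    return v


@dataclass
class PipelineData:
    """Everything a stage may need, loaded once."""

    genome: dict[str, str] | None = None
    chrom_sizes: dict[str, int] | None = None
    genes: list | None = None
    peaks: list | None = None
    counts: iof.CountMatrix | None = None
    deg_tables: dict[str, iof.DEGTable] = field(default_factory=dict)
    pif4_targets: set[str] | None = None
    truth: sd.TruthBundle | None = None
    links: list | None = None
    diffbind: pd.DataFrame | None = None
    motif_hits: dict[str, list] = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config, outdir: Path, seed: int, data: PipelineData) -> dict:
    sim_cfg = sd.SimConfig(**{**config.get("simulate", {}), "seed": seed})
    sim = sd.simulate_all(sim_cfg)
    paths = sd.write_outputs(sim, outdir / "simulated")
    data.genome = sim.genome
    data.chrom_sizes = sim.chrom_sizes
    data.genes = sim.genes
    data.peaks = sim.peaks
    data.counts = sim.counts
    data.deg_tables = sim.deg_tables
    data.pif4_targets = sim.pif4_targets
    data.truth = sim.truth
    return {
        "n_chrom": sim_cfg.n_chrom,
        "n_genes": len(sim.genes),
        "n_peaks": len(sim.peaks),
        "n_cooperative_planted": len(sim.truth.cooperative_genes),
        "outputs": {k: str(v) for k, v in paths.items()},
    }


def stage_load(config, data: PipelineData) -> dict:
    inputs = config["inputs"]
    data.genome = iof.read_fasta(inputs["genome"])
    data.chrom_sizes = {c: len(s) for c, s in data.genome.items()}
    data.genes = iof.read_genes(inputs["genes"])
    data.peaks = iof.read_peaks(
        inputs["peaks"], dialect=inputs.get("peaks_dialect", "narrowPeak")
    )
    if inputs.get("counts"):
        data.counts = iof.read_count_matrix(inputs["counts"])
    for gt, path in (inputs.get("deg_tables") or {}).items():
        data.deg_tables[gt] = iof.read_deg_table(path)
    if inputs.get("pif4_targets"):
        data.pif4_targets = set(
            pd.read_csv(inputs["pif4_targets"], sep="\t")["gene_id"].astype(str)
        )
    return {
        "n_genes": len(data.genes),
        "n_peaks": len(data.peaks),
        "have_counts": data.counts is not None,
        "deg_tables": list(data.deg_tables),
    }


def stage_annotate(config, outdir: Path, seed: int, data: PipelineData) -> dict:
    ann = config["annotation"]
    cfg = pa.AnnotationConfig(
        upstream_window=ann["upstream_window"],
        downstream_window=ann["downstream_window"],
        anchor=ann["anchor"],
    )
    links = pa.assign_peaks_to_genes(data.peaks, data.genes, cfg)
    data.links = links
    pd.DataFrame(
        [(l.peak_id, l.gene_id, l.category, l.signed_distance) for l in links],
        columns=["peak_id", "gene_id", "category", "signed_distance"],
    ).to_csv(outdir / "links.tsv", sep="\t", index=False)
    profile = pa.metagene_profile(data.peaks, data.genes, cfg, bins=ann["bins"])
    envelope = pa.random_peak_null(
        data.peaks,
        data.chrom_sizes,
        data.genes,
        cfg,
        n_sets=ann["n_sets"],
        seed=seed,
        bins=ann["bins"],
    )
    prof_df = pd.DataFrame(
        {
            "bin_lo": profile.bin_edges[:-1],
            "bin_hi": profile.bin_edges[1:],
            "observed": profile.observed_density,
            "null_mean": envelope.mean,
            "null_lo95": envelope.lo95,
            "null_hi95": envelope.hi95,
        }
    )
    prof_df.to_csv(outdir / "metagene_profile.tsv", sep="\t", index=False)
    upstream_3kb = {
        l.peak_id
        for l in links
        if l.category == "upstream" and -3000 <= l.signed_distance < 0
    }
    return {
        "n_links": len(links),
        "n_peaks_linked": len({l.peak_id for l in links}),
        "n_genes_linked": len({l.gene_id for l in links}),
        "pct_peaks_within_3kb_upstream": 100.0 * len(upstream_3kb) / len(data.peaks),
        "n_null_sets": envelope.n_sets,
    }


def stage_motifs(config, outdir: Path, data: PipelineData) -> dict:
    specs = [ma.MotifSpec(m["name"], m["consensus"]) for m in config["motifs"]]
    peak_seqs = {
        p.id: data.genome[p.interval.chrom][p.interval.start : p.interval.end]
        for p in data.peaks
    }
    target_genes = {l.gene_id for l in data.links} if data.links else set()
    summary: dict[str, Any] = {}
    all_rows = []
    for spec in specs:
        hits = [
            h
            for rid, seq in peak_seqs.items()
            for h in ma.scan_motif(seq, spec, rid)
        ]
        data.motif_hits[spec.name] = hits
        all_rows.extend((h.region_id, h.motif_name, h.offset, h.strand) for h in hits)
        counts = ma.motif_counts_per_peak(hits, data.peaks) if hits else {
            spec.name: {0: len(data.peaks)}
        }
        spacing = ma.spacing_distances(hits)
        enrich = ma.central_enrichment(hits, data.peaks, spec)
        entry = {
            "n_hits": len(hits),
            "counts_per_peak": counts.get(spec.name, {}),
            "spacing_n": len(spacing.distances),
            "spacing_mode_bp": spacing.mode_estimate,
            "central_enrichment": [
                {
                    "halfwidth": r.window_halfwidth,
                    "hits_in_window": r.hits_in_window,
                    "hits_total": r.hits_total,
                    "expected_fraction": r.expected_fraction,
                    "p_adjusted": r.p,
                    "best": r.best,
                }
                for r in enrich
            ],
        }
        if target_genes and len(target_genes) < len(data.genes):
            bg = ma.background_spacing(
                data.genes,
                target_genes,
                data.genome,
                spec,
                promoter_window=config.get("background_promoter_window", 1000),
            )
            entry["background_spacing_mode_bp"] = bg.mode_estimate
            entry["background_spacing_n"] = len(bg.distances)
        summary[spec.name] = entry
    pd.DataFrame(
        all_rows, columns=["region_id", "motif", "offset", "strand"]
    ).to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
    _write_json(summary, outdir / "motif_summary.json")
    return summary


def stage_stratify(config, outdir: Path, data: PipelineData) -> dict:
    strat = config["stratify"]
    alpha = config["thresholds"]["alpha"]
    summary = {}
    for spec_cfg in config["motifs"]:
        name = spec_cfg["name"]
        hits = data.motif_hits.get(name, [])
        per_peak: dict[str, int] = {}
        for h in hits:
            per_peak[h.region_id] = per_peak.get(h.region_id, 0) + 1
        groups = os_.stratify_by_motif_count(
            data.peaks, per_peak, max_group=strat["max_group"]
        )
        if len(groups) < 2:
            summary[name] = {"skipped": "fewer than 2 motif-count groups"}
            continue
        res = os_.pairwise_letters(groups, alpha=alpha)
        summary[name] = {
            "group_sizes": {k: len(v) for k, v in res.groups.items()},
            "kw_H": res.kw_H,
            "kw_p": res.kw_p,
            "letters": res.letters,
            "pairwise_fdr": {f"{a}|{b}": p for (a, b), p in res.pairwise.items()},
        }
    _write_json(summary, outdir / "stratify.json")
    return summary


def stage_diffbind(config, outdir: Path, data: PipelineData) -> dict:
    res = os_.differential_binding(
        data.counts, fdr_threshold=config["thresholds"]["fdr"]
    )
    data.diffbind = res
    res.to_csv(outdir / "diffbind.tsv", sep="\t", index=False)
    sig = res[res["significant"]]
    return {
        "n_peaks": len(res),
        "n_significant": int(len(sig)),
        "n_significant_down": int((sig["log2fc"] < 0).sum()),
        "n_significant_up": int((sig["log2fc"] > 0).sum()),
    }


def stage_coregulate(config, outdir: Path, data: PipelineData) -> dict:
    th = config["thresholds"]
    deg_cfg = cr.DEGFilterConfig(
        fold_change_threshold=th["fold_change"], padj_threshold=th["padj"]
    )
    genotypes = list(data.deg_tables)
    degs = {gt: cr.filter_degs(data.deg_tables[gt], deg_cfg) for gt in genotypes}
    universe = set.intersection(
        *[set(data.deg_tables[gt].records["gene_id"].astype(str)) for gt in genotypes]
    )
    a, b = genotypes[0], genotypes[1]
    shared = set(degs[a]) & set(degs[b])
    ov = cr.overlap_test(set(degs[a]) & universe, set(degs[b]) & universe, universe)
    dc = cr.direction_consistency(degs[a], degs[b])

    gene_of_peak: dict[str, set[str]] = {}
    for l in data.links or []:
        gene_of_peak.setdefault(l.peak_id, set()).add(l.gene_id)
    bound_by_cdf2 = set().union(*gene_of_peak.values()) if gene_of_peak else set()
    reduced = set()
    if data.diffbind is not None:
        down = data.diffbind[
            data.diffbind["significant"] & (data.diffbind["log2fc"] < 0)
        ]
        for pid in down["peak_id"]:
            reduced |= gene_of_peak.get(pid, set())
    coop = cr.cooperative_genes(
        shared, bound_by_cdf2, data.pif4_targets or set(), reduced
    )
    pd.DataFrame(
        [(g, ";".join(coop.provenance[g])) for g in coop.gene_ids],
        columns=["gene_id", "evidence_layers"],
    ).to_csv(outdir / "cooperative_genes.tsv", sep="\t", index=False)
    summary = {
        "n_deg": {gt: len(degs[gt]) for gt in genotypes},
        "n_shared_degs": len(shared),
        "overlap_p": ov.p,
        "n_universe": ov.n_universe,
        "direction": {
            "n_same_up": dc.n_same_up,
            "n_same_down": dc.n_same_down,
            "n_opposite": dc.n_opposite,
            "fraction_opposite": dc.fraction_opposite,
        },
        "n_bound_by_cdf2": len(bound_by_cdf2),
        "n_bound_by_pif4": len(data.pif4_targets or set()),
        "n_reduced_binding_genes": len(reduced),
        "cooperative_genes": coop.gene_ids,
        "n_cooperative": len(coop.gene_ids),
    }
    _write_json(summary, outdir / "coregulation.json")
    return summary


def run_all(
    config: Mapping[str, Any], outdir, seed: int | None = None, until: str | None = None
) -> dict:
    """Run the stages in order; returns (and writes) the run report.

    ``until`` names the last stage to execute (inclusive); later stages are
    reported as not run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    try:
        pkg_version = _pkg_version("cobind")
    except Exception:
        pkg_version = "unknown"
    report: dict[str, Any] = {
        "seed": seed,
        "version": pkg_version,
        "config": _jsonable(dict(config)),
        "stages": {},
    }
    data = PipelineData()

    def run_stage(name, fn, *args):
        t0 = time.time()
        logger.info("[%s] start", name)
        try:
            out = fn(*args)
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        out = dict(out)
        out["seconds"] = round(time.time() - t0, 3)
        report["stages"][name] = out
        logger.info("[%s] done in %.1fs", name, out["seconds"])

    order = ["simulate", "annotate", "motifs", "stratify", "diffbind", "coregulate"]
    last = order.index(until) if until in order else len(order) - 1

    if "simulate" in config:
        run_stage("simulate", stage_simulate, config, outdir, seed, data)
    else:
        run_stage("load", stage_load, config, data)
    for name in order[1 : last + 1]:
        if name == "annotate":
            run_stage("annotate", stage_annotate, config, outdir, seed, data)
        elif name == "motifs":
            run_stage("motifs", stage_motifs, config, outdir, data)
        elif name == "stratify":
            run_stage("stratify", stage_stratify, config, outdir, data)
        elif name == "diffbind":
            if data.counts is not None:
                run_stage("diffbind", stage_diffbind, config, outdir, data)
            else:
                report["stages"]["diffbind"] = {"skipped": "no counts"}
        elif name == "coregulate":
            if len(data.deg_tables) == 2:
                run_stage("coregulate", stage_coregulate, config, outdir, data)
            else:
                report["stages"]["coregulate"] = {"skipped": "need 2 DEG tables"}
    report = _jsonable(report)
    _write_json(report, outdir / "report.json")
    return report
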