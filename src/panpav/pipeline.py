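"""End-to-end pipeline: simulate -> augment -> PAV -> analytics -> popgen.

A single YAML-able config drives every stage; unknown keys are rejected
before anything runs and every threshold defaults to the pipeline's
standard printed values (identity 0.90 / 100 bp; breadth 0.99 / depth 3x;
occupancy bands 0.99 / 0.90 / 0.15; 1,000-kb window / 100-kb step; top 5%
score / top 50% ROD; K = 8).  One global seed is fanned out to per-stage
seeds by fixed offsets so stages can be rerun independently yet
reproducibly.  Every output file is listed in a manifest with its content
hash; identical config + seed gives identical manifest hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats as io
from . import pav_analysis, pav_structure, popgen, simdata
from .pan_augment import augment_iterative
from .pav_build import build_pav_matrix, greedy_cluster_genes

logger = logging.getLogger("panpav")

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline",
           "demo_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


_SIM_FIELDS = {f.name for f in dataclasses.fields(simdata.SimConfig)}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},          # overrides for SimConfig fields
    "augment": {"identity_min": 0.90, "aligned_len_min": 100,
                "min_retained_len": 100, "k": 21},
    "pav": {"breadth_min": 0.99, "depth_min": 3.0, "cluster_identity": 0.90},
    "curves": {"n_perm": 30},
    "structure": {"metric": "simple-matching", "ward_k": 8, "ward_axis": "rows"},
    "popgen": {"window": popgen.WINDOW_DEFAULT, "step": popgen.STEP_DEFAULT,
               "ld_max_dist": 200_000, "ld_bin_width": 5_000},
    "sweep": {"top_score": 0.05, "top_rod": 0.50},
}


def _merged(defaults: dict, overrides: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in defaults.items()}
    for key, val in overrides.items():
        if key == "simulate":
            unknown = set(val) - _SIM_FIELDS
            if unknown:
                raise PipelineError(
                    f"unknown simulate config keys {sorted(unknown)}")
            out[key] = dict(val)
        elif key not in defaults:
            raise PipelineError(f"unknown config key {key!r}")
        elif isinstance(defaults[key], dict):
            sub = dict(defaults[key])
            for k2, v2 in val.items():
                if k2 not in sub:
                    raise PipelineError(f"unknown config key {key}.{k2!r}")
                sub[k2] = v2
            out[key] = sub
        else:
            out[key] = val
    return out


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config (YAML path or dict)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    return _merged(DEFAULT_CONFIG, raw)


def demo_config() -> dict:
    """A small complete configuration that runs in minutes on one CPU."""
    return load_config({
        "simulate": {
            "groups": (("PS", 6), ("PF", 5), ("PA", 4)),
            "n_core_genes": 60, "n_softcore": 20, "n_shell": 80,
            "n_cloud": 60,
            "group_preferred": {"PS": 10, "PF": 10, "PA": 10},
            "chrom_length": 2_000_000, "n_sites": 3_000,
            "n_contigs_per_accession": 2,
            "contig_length_range": (40_000, 80_000),
            "sweep_specs": (simdata.SweepSpec(600_000, 900_000, 10.0, 0.2),),
            "track_window": 200_000, "track_step": 50_000,
        },
        "popgen": {"window": 200_000, "step": 50_000,
                   "ld_max_dist": 100_000, "ld_bin_width": 5_000},
        "curves": {"n_perm": 30},
    })


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _reconcile_cluster_ids(clusters) -> None:
    """Name each greedy cluster after the majority pan-gene id its member
    gene names carry (gene ids are "<accession>.<pangene>"); split clusters
    mapping to an already-used name get a numbered suffix."""
    used: set[str] = set()
    for cl in clusters:
        votes: dict[str, int] = {}
        for _acc, gid in cl.members:
            key = gid.rsplit(".", 1)[-1]
            votes[key] = votes.get(key, 0) + 1
        best = max(sorted(votes), key=lambda k: votes[k])
        name = best
        suffix = 1
        while name in used:
            name = f"{best}_{suffix}"
            suffix += 1
        used.add(name)
        cl.cluster_id = name


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage in dependency order; returns the artifact manifest.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    stage = "simulate"
    try:
        sim_kwargs = dict(cfg["simulate"])
        if "groups" in sim_kwargs:
            sim_kwargs["groups"] = tuple(
                (str(g), int(n)) for g, n in sim_kwargs["groups"])
        if sim_kwargs.get("sweep_specs") is not None:
            sim_kwargs["sweep_specs"] = tuple(
                s if isinstance(s, simdata.SweepSpec) else simdata.SweepSpec(*s)
                for s in sim_kwargs["sweep_specs"])
        for key in ("contig_length_range", "gene_length_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_cfg = simdata.SimConfig(seed=cfg["seed"], **sim_kwargs)
        art = simdata.simulate_all(sim_cfg)
        io.write_fasta([art["reference"]], emit(out / "reference.fa"))
        asm_dir = out / "assemblies"
        asm_dir.mkdir(exist_ok=True)
        for acc, contigs in art["assemblies"].items():
            io.write_fasta(contigs, emit(asm_dir / f"{acc}.fa"))
        io.write_vcf(art["genotypes"], emit(out / "genotypes.vcf"),
                     {sim_cfg.chrom_name: sim_cfg.chrom_length})
        io.write_coverage_tsv(art["coverage"], emit(out / "coverage.tsv"))
        io.write_labels_tsv(sim_cfg.labels, emit(out / "labels.tsv"))
        io.write_window_track(art["score_track"], emit(out / "score.tsv"))
        io.write_window_track(art["pi_wild"], emit(out / "pi_wild.tsv"))
        io.write_window_track(art["pi_dom"], emit(out / "pi_dom.tsv"))
        art["truth"].to_json(emit(out / "truth.json"))
        pd.DataFrame(art["genes"], columns=["accession", "gene_id", "seq"]).to_csv(
            emit(out / "genes.tsv"), sep="\t", index=False)
        with open(emit(out / "term_map.tsv"), "w") as fh:
            fh.write("gene\tterms\n")
            for g, ts in art["term_map"].items():
                fh.write(f"{g}\t{','.join(ts)}\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "augment"
    try:
        pan, report = augment_iterative(
            [art["reference"]], art["assemblies"],
            identity_min=cfg["augment"]["identity_min"],
            aligned_len_min=cfg["augment"]["aligned_len_min"],
            min_retained_len=cfg["augment"]["min_retained_len"],
            k=cfg["augment"]["k"])
        io.write_fasta(pan.to_records(), emit(out / "pan.fa"))
        report.to_csv(emit(out / "augment_report.tsv"), sep="\t", index=False,
                      float_format="%.6g")
        pan.provenance_frame().to_csv(emit(out / "pan_provenance.tsv"),
                                      sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "pav"
    try:
        clusters = greedy_cluster_genes(
            art["genes"], identity_threshold=cfg["pav"]["cluster_identity"])
        _reconcile_cluster_ids(clusters)
        known = {c.cluster_id for c in clusters}
        coverage = [r for r in art["coverage"] if r.cluster_id in known]
        pav = build_pav_matrix(clusters, coverage, sim_cfg.labels,
                               breadth_min=cfg["pav"]["breadth_min"],
                               depth_min=cfg["pav"]["depth_min"])
        io.write_pav_tsv(pav.matrix, emit(out / "pav.tsv"))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "classify"
    try:
        table, totals = pav_analysis.classify_pan_genes(pav)
        table.to_csv(emit(out / "classes.tsv"), sep="\t",
                     index_label="cluster_id", float_format="%.6g")
        totals.to_frame("n_clusters").to_csv(emit(out / "class_totals.tsv"),
                                             sep="\t", index_label="class")
        curve = pav_analysis.pan_core_curves(pav, n_perm=cfg["curves"]["n_perm"],
                                             seed=cfg["seed"] + 17)
        curve.to_frame().to_csv(emit(out / "curves.tsv"), sep="\t", index=False,
                                float_format="%.6g")
        fit = pav_analysis.fit_saturation_models(curve)
        with open(emit(out / "curve_fit.json"), "w") as fh:
            json.dump({
                "pan_params": fit.pan_params, "core_params": fit.core_params,
                "pan_residual": fit.pan_residual,
                "core_residual": fit.core_residual,
                "verdict": fit.verdict, "flags": fit.flags,
            }, fh, indent=1, sort_keys=True)
        unique = pav_analysis.unique_group_genes(pav)
        with open(emit(out / "unique_genes.json"), "w") as fh:
            json.dump(unique, fh, indent=1, sort_keys=True)
        background = set(pav.matrix.index)
        for group, d in sorted(unique.items()):
            fg = set(d["unique_pan"]) & background
            if fg:
                enr = pav_analysis.enrich_terms(fg, background, art["term_map"])
                enr.to_csv(emit(out / f"enrich_{group}.tsv"), sep="\t",
                           index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "structure"
    try:
        dist = pav_structure.pav_distance(pav, metric=cfg["structure"]["metric"])
        tree = pav_structure.nj_tree(dist)
        io.write_newick(tree, emit(out / "pav_nj.nwk"))
        ward = pav_structure.ward_cluster(pav.matrix, k=cfg["structure"]["ward_k"],
                                          axis=cfg["structure"]["ward_axis"])
        ward.labels.to_frame().to_csv(emit(out / "ward_clusters.tsv"), sep="\t",
                                      index_label="id")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "popgen"
    try:
        geno = art["genotypes"]
        chrom_lengths = {sim_cfg.chrom_name: sim_cfg.chrom_length}
        for group, _n in sim_cfg.groups:
            members = [a for a in geno.samples if sim_cfg.labels[a] == group]
            track = popgen.window_pi(geno, members, cfg["popgen"]["window"],
                                     cfg["popgen"]["step"], chrom_lengths)
            io.write_window_track(track, emit(out / f"pi_{group}.tsv"))
        genome_fst, fst_track = popgen.weir_cockerham_fst(
            geno, sim_cfg.labels,
            windows=(cfg["popgen"]["window"], cfg["popgen"]["step"]),
            chrom_lengths=chrom_lengths)
        io.write_window_track(fst_track, emit(out / "fst.tsv"))
        curve_ld, half = popgen.ld_decay(
            geno, max_dist=cfg["popgen"]["ld_max_dist"],
            bin_width=cfg["popgen"]["ld_bin_width"])
        curve_ld.to_csv(emit(out / "ld_decay.tsv"), sep="\t", index=False,
                        float_format="%.6g")
        import math as _math
        with open(emit(out / "popgen_summary.json"), "w") as fh:
            json.dump({"genome_fst": genome_fst,
                       "ld_half_decay_bp": None if _math.isnan(half) else half},
                      fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "sweep"
    try:
        sweeps, audit = popgen.sweep_filter(
            art["score_track"], art["pi_wild"], art["pi_dom"],
            top_score=cfg["sweep"]["top_score"], top_rod=cfg["sweep"]["top_rod"])
        io.write_bed([(s.chrom, s.start, s.end, f"sweep{i + 1}")
                      for i, s in enumerate(sweeps)], emit(out / "sweeps.bed"))
        for name, df in audit.items():
            df.to_csv(emit(out / f"sweep_audit_{name}.tsv"), sep="\t",
                      index=False, float_format="%.10g")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(files)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
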