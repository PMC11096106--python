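"""End-to-end pipeline: simulate -> classify -> syndiv -> svmerge -> censize -> report.

One YAML config (one artifact of record) drives every stage; each stage
writes its outputs plus a manifest entry (inputs, parameters, seed, sha256
content digest). Re-running with an identical config reproduces identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import censize, io_formats, panclass, svmerge, syndiv, synthetic
from .records import DepthTrack
from .synthetic import SimConfig

logger = logging.getLogger("pansynkit.pipeline")

STAGES = ("simulate", "classify", "syndiv", "svmerge", "censize", "report")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 42
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: SimConfig = field(default_factory=SimConfig)
    # stage parameters
    softcore_fraction: float = 0.90
    cov_threshold: float = 0.95
    rarefaction_replicates: int = 2000
    window: int = 100_000
    step: int = 50_000
    pi_low: float = 0.2
    pi_high: float = 0.5
    large_sv_min_len: int = 1_000_000
    repeat_accessions: int | None = None  # subset for the sequence/depth stage
    truncation: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    seed = raw.get("seed", 42)
    sim_raw.setdefault("seed", seed)
    known = {f.name for f in fields(SimConfig)}
    unknown = set(sim_raw) - known
    if unknown:
        raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
    if "category_props" in sim_raw:
        sim_raw["category_props"] = tuple(sim_raw["category_props"])
    for key in ("inversion_size_range", "copy_range"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    if "centromere_spans" in sim_raw:
        sim_raw["centromere_spans"] = {
            c: tuple(v) for c, v in sim_raw["centromere_spans"].items()
        }
    sim = SimConfig(**sim_raw)
    known_pipe = {f.name for f in fields(PipelineConfig)} - {"sim"}
    unknown = set(raw) - known_pipe
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(sim=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig) -> None:
        self.outdir = outdir
        self.entries: dict[str, dict] = {}
        self.meta = {"seed": config.seed, "stages": list(config.stages)}

    def record(self, stage: str, path: Path, params: dict | None = None) -> None:
        rel = str(path.relative_to(self.outdir))
        self.entries[rel] = {
            "stage": stage,
            "sha256": _sha256(path),
            "params": params or {},
        }

    def fail(self, stage: str, error: str) -> None:
        self.meta["failed_stage"] = stage
        self.meta["error"] = error

    def write(self) -> None:
        payload = {"meta": self.meta, "files": self.entries}
        (self.outdir / "manifest.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )


def _validate_inputs(config: PipelineConfig) -> None:
    """Referenced inputs must exist before any stage runs."""
    d = config.outdir
    need: dict[str, list[Path]] = {}
    if "classify" in config.stages and "simulate" not in config.stages:
        need["classify"] = [d / "orthogroups.tsv", d / "hits.tsv"]
    if "syndiv" in config.stages and "simulate" not in config.stages:
        need["syndiv"] = [d / "syri"]
    if "svmerge" in config.stages and "simulate" not in config.stages:
        need["svmerge"] = [d / "sv_records.tsv"]
    if "censize" in config.stages and "simulate" not in config.stages:
        need["censize"] = [d / "fasta", d / "depth"]
    missing = [
        f"{stage}: {p}" for stage, paths in need.items() for p in paths if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(
            "stage inputs missing (enable the simulate stage or provide them): "
            + "; ".join(missing)
        )


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report."""
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    _validate_inputs(config)
    manifest = Manifest(outdir, config)
    report: dict = {"seed": config.seed}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t0 = time.monotonic()
            logger.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](config, manifest, report)
            logger.info("stage %s done in %.1fs", stage, time.monotonic() - t0)
    except Exception as exc:  # partial outputs retained, manifest marks failure
        manifest.fail(stage, repr(exc))
        manifest.write()
        raise
    manifest.write()
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    sim = config.sim
    pav, truth = synthetic.simulate_pav(sim)
    hits = synthetic.simulate_homology(pav, truth, sim)
    blocks, truth = synthetic.simulate_synteny(sim, truth)
    n_rep = config.repeat_accessions or min(sim.n_accessions, 10)
    rep = synthetic.simulate_repeats_and_depth(
        sim, truth, n_accessions=n_rep, truncation=config.truncation
    )
    truth = rep.truth

    io_formats.write_orthogroups(truth.orthogroups_observed, d / "orthogroups.tsv")
    manifest.record("simulate", d / "orthogroups.tsv")
    io_formats.write_hits(hits, d / "hits.tsv")
    manifest.record("simulate", d / "hits.tsv")
    io_formats.write_pav(pav, d / "pav_true.tsv")
    manifest.record("simulate", d / "pav_true.tsv")

    gff_dir = d / "gff"
    gff_dir.mkdir(exist_ok=True)
    by_acc: dict[str, list] = {}
    for g in truth.gene_models.values():
        by_acc.setdefault(g.accession, []).append(g)
    for acc, genes in sorted(by_acc.items()):
        io_formats.write_gff3(genes, gff_dir / f"{acc}.gff3")
        manifest.record("simulate", gff_dir / f"{acc}.gff3")

    syri_dir = d / "syri"
    syri_dir.mkdir(exist_ok=True)
    for acc, blk in sorted(blocks.items()):
        io_formats.write_syri(blk, syri_dir / f"{acc}.syri.tsv")
        manifest.record("simulate", syri_dir / f"{acc}.syri.tsv")

    all_svs = [r for recs in truth.planted_svs.values() for r in recs]
    io_formats.write_sv_records(all_svs, d / "sv_records.tsv")
    manifest.record("simulate", d / "sv_records.tsv")

    fasta_dir, depth_dir = d / "fasta", d / "depth"
    fasta_dir.mkdir(exist_ok=True)
    depth_dir.mkdir(exist_ok=True)
    for acc in sorted(rep.sequences):
        io_formats.write_fasta(rep.sequences[acc], fasta_dir / f"{acc}.fa")
        manifest.record("simulate", fasta_dir / f"{acc}.fa")
        io_formats.write_depth(rep.genome_depth[acc], depth_dir / f"{acc}.genome.depth.tsv")
        manifest.record("simulate", depth_dir / f"{acc}.genome.depth.tsv")
        io_formats.write_depth(
            {rep.concatemer_depth[acc].chrom: rep.concatemer_depth[acc]},
            depth_dir / f"{acc}.concatemer.depth.tsv",
        )
        manifest.record("simulate", depth_dir / f"{acc}.concatemer.depth.tsv")

    synthetic.truth_to_json(truth, d / "truth.json")
    manifest.record("simulate", d / "truth.json")
    report["simulate"] = {
        "n_accessions": sim.n_accessions,
        "n_families": sim.n_families,
        "repeat_accessions": n_rep,
    }


def _stage_classify(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    table = io_formats.read_orthogroups(d / "orthogroups.tsv")
    hits = io_formats.read_hits(d / "hits.tsv")
    fused = panclass.fuse_orthogroups(table, hits, config.cov_threshold)

    gene_models = {}
    gff_dir = d / "gff"
    if gff_dir.is_dir():
        for path in sorted(gff_dir.glob("*.gff3")):
            for g in io_formats.read_gff3(path, accession=path.name.split(".")[0]):
                gene_models[g.gene_id] = g
    matrix = panclass.matrix_from_orthogroups(fused)
    rules = panclass.ClassificationRules(config.softcore_fraction)
    labels, counts = panclass.classify(matrix, rules)
    comp = panclass.composition(matrix, labels)
    flags = (
        panclass.flag_split_merge(fused, gene_models, hits, config.cov_threshold)
        if gene_models
        else pd.Series(False, index=matrix.index, name="split_merge")
    )

    cat_df = pd.DataFrame({"category": labels, "split_merge": flags})
    cat_df.to_csv(d / "categories.tsv", sep="\t", index_label="family")
    manifest.record("classify", d / "categories.tsv", {"softcore_fraction": config.softcore_fraction})
    comp.to_csv(d / "composition.tsv", sep="\t", index_label="accession")
    manifest.record("classify", d / "composition.tsv")
    curve = panclass.rarefaction_mc(
        matrix,
        replicates=config.rarefaction_replicates,
        seed=config.seed,
    )
    curve.to_csv(d / "rarefaction.tsv", sep="\t")
    manifest.record(
        "classify", d / "rarefaction.tsv",
        {"replicates": config.rarefaction_replicates, "seed": config.seed},
    )
    report["classify"] = {
        "category_counts": counts,
        "n_families_fused": fused.n_families,
        "n_split_merge": int(flags.sum()),
    }


def _stage_syndiv(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    blocks = {}
    for path in sorted((d / "syri").glob("*.syri.tsv")):
        acc = path.name.split(".")[0]
        blocks[acc] = io_formats.read_syri(path, acc)
    lengths = dict(config.sim.ref_chrom_lengths)
    indicator = syndiv.project_synteny(blocks, lengths)
    stats = syndiv.synteny_diversity(
        indicator, lengths, syndiv.WindowSpec(config.window, config.step)
    )
    stats.to_csv(d / "synteny_diversity.tsv", sep="\t", index=False)
    manifest.record(
        "syndiv", d / "synteny_diversity.tsv",
        {"window": config.window, "step": config.step},
    )
    low, high = syndiv.fraction_by_threshold(stats, config.pi_low, config.pi_high)
    report["syndiv"] = {
        "fraction_below": low,
        "fraction_above": high,
        "low": config.pi_low,
        "high": config.pi_high,
        "n_windows": int(len(stats)),
    }


def _stage_svmerge(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    records = io_formats.read_sv_records(d / "sv_records.tsv")
    out = {}
    for tier, params in (
        ("small", svmerge.MergeParams.small_tier()),
        ("large", svmerge.MergeParams.large_tier()),
    ):
        tier_records = [r for r in records if params.in_bounds(r.length)]
        clusters = svmerge.merge_svs(tier_records, params)
        frame = svmerge.clusters_to_frame(clusters)
        frame.to_csv(d / f"sv_merged_{tier}.tsv", sep="\t", index=False)
        manifest.record(
            "svmerge", d / f"sv_merged_{tier}.tsv",
            {"max_dist": params.max_dist},
        )
        summary = svmerge.sv_summary(clusters)
        out[tier] = {
            "n_clusters": summary["n_clusters"],
            "support_spectrum": summary["support_spectrum"],
        }
        if tier == "large":
            big = svmerge.find_large_rearrangements(clusters, config.large_sv_min_len)
            out["large_rearrangements"] = [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "type": c.sv_type,
                    "length": c.length,
                    "support": c.support,
                    "accessions": c.accessions,
                }
                for c in big
            ]
    report["svmerge"] = out


def _stage_censize(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    sim = config.sim
    cen_params = censize.RepeatParams(motif=sim.motif_cen)
    tel_params = censize.RepeatParams(motif=sim.motif_tel, min_copies=5)
    rows = []
    array_rows = []
    for fa in sorted((d / "fasta").glob("*.fa")):
        acc = fa.stem
        seqs = io_formats.read_fasta(fa)
        tracks = io_formats.read_depth(d / "depth" / f"{acc}.genome.depth.tsv")
        conc = io_formats.read_depth(d / "depth" / f"{acc}.concatemer.depth.tsv")
        conc_track = next(iter(conc.values()))
        per_chrom_assembled = {}
        mask = {}
        for chrom, seq in seqs.items():
            arrays = censize.find_repeat_arrays(seq, cen_params, chrom=chrom)
            per_chrom_assembled[chrom] = sum(a.length for a in arrays)
            mask[chrom] = [(a.start, a.end) for a in arrays]
            for a in arrays:
                array_rows.append(
                    (acc, "cen", a.chrom, a.start, a.end, a.strand, a.copy_estimate)
                )
            for a in censize.find_repeat_arrays(seq, tel_params, chrom=chrom):
                array_rows.append(
                    (acc, "tel", a.chrom, a.start, a.end, a.strand, a.copy_estimate)
                )
        mean_depth = censize.genome_mean_depth(tracks, mask)
        estimate = censize.estimate_repeat_length(conc_track, mean_depth)
        assembled = sum(per_chrom_assembled.values())
        rows.append(
            (
                acc,
                sum(len(s) for s in seqs.values()),
                assembled,
                estimate,
                censize.completeness_ratio(assembled, estimate),
            )
        )
    size_table = pd.DataFrame(
        rows,
        columns=["accession", "assembly_size", "repeat_assembled", "repeat_estimate", "completeness"],
    ).set_index("accession")
    pd.DataFrame(
        array_rows,
        columns=["accession", "motif", "chrom", "start", "end", "strand", "copy_estimate"],
    ).to_csv(d / "repeat_arrays.tsv", sep="\t", index=False)
    manifest.record("censize", d / "repeat_arrays.tsv")
    size_table.to_csv(d / "size_table.tsv", sep="\t")
    manifest.record("censize", d / "size_table.tsv")
    report["censize"] = {"mean_completeness": float(size_table["completeness"].mean())}
    if len(size_table) >= 3:  # Pearson r needs >= 3 accessions
        corr = censize.size_correlations(
            size_table,
            [("assembly_size", "repeat_assembled"), ("assembly_size", "repeat_estimate")],
        )
        corr.to_csv(d / "size_correlations.tsv", sep="\t", index=False)
        manifest.record("censize", d / "size_correlations.tsv")
        report["censize"]["r_assembly_vs_repeat"] = float(corr["r"].iloc[0])


def _stage_report(config: PipelineConfig, manifest: Manifest, report: dict) -> None:
    d = config.outdir
    (d / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    manifest.record("report", d / "report.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "syndiv": _stage_syndiv,
    "svmerge": _stage_svmerge,
    "censize": _stage_censize,
    "report": _stage_report,
}
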