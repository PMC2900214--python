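"""End-to-end orchestration: synth -> pseudogene calls -> IS scan ->
erosion statistics -> COG enrichment -> gene-set status, with a
machine-readable report.

A single YAML config drives a run; the resolved config is written next to
the outputs for provenance.  All stochastic stages take their seed from the
config, so identical config + seed produces identical report content.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import cog_enrichment, erosion_stats, genome_io, is_detector
from . import geneset_compare, pseudo_caller, synthetic_data

log = logging.getLogger("erosionscan")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "erosionscan_out"
    genome: Optional[str] = None
    features: Optional[str] = None
    refs: Optional[str] = None
    is_library: Optional[str] = None
    gene_set_tsv: Optional[str] = None
    gene_set_fasta: Optional[str] = None
    gene_set_name: str = "custom"
    caller: dict = field(default_factory=dict)
    is_config: dict = field(default_factory=dict)
    enrichment_B: int = 2000
    seed: int = 0
    synth: Optional[dict] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f: data[f] for f in data if f in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if self.synth is None:
            for name in ("genome", "features", "refs"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"config field {name!r} is required "
                                      "when no synth block is given")
                if not Path(p).exists():
                    raise ConfigError(f"config field {name!r}: "
                                      f"path {p} does not exist")
        for name in ("is_library", "gene_set_tsv", "gene_set_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path {p} "
                                  "does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(outdir: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the report dict.

    Stage failures propagate with the stage named; report content is
    deterministic for fixed config + seed (timings go to run.log only).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, cfg.log_level)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrap

    report: dict = {"seed": cfg.seed}

    if cfg.synth is not None:
        synth_cfg = synthetic_data.SynthConfig(**{**cfg.synth, "seed": cfg.seed})
        bundle = stage("synth")(synthetic_data.write_synthetic,
                                synth_cfg, outdir / "synth")
        genome = bundle["genome"]
        features = bundle["features"]
        refs = bundle["ref_proteome"]
        library = dict(bundle["truth"].is_families)
    else:
        genome = stage("load")(genome_io.read_fasta, cfg.genome)
        features = genome_io.read_gff(cfg.features, genome)
        refs = genome_io.read_protein_fasta(cfg.refs)
        library = (genome_io.read_protein_fasta(cfg.is_library)
                   if cfg.is_library else {})

    caller_cfg = pseudo_caller.CallerConfig(**cfg.caller)
    called, calls = stage("callpseudo")(
        pseudo_caller.call_pseudogenes, genome, features, refs, caller_cfg)
    log.info("pseudogene calls: %d", len(calls))

    is_cfg = is_detector.ISConfig(**cfg.is_config)
    families = stage("isscan.repeats")(
        is_detector.find_repeat_families, genome, is_cfg)
    if not library:
        library = {f.family_id: f.consensus for f in families}
    if library:
        hits = stage("isscan.homology")(
            is_detector.scan_homology, genome, library, is_cfg)
        remnants = is_detector.merge_fragments(hits, families, is_cfg)
        n_orfs, n_long, orf_table = is_detector.census_transposase_orfs(
            genome, remnants, is_cfg, families)
    else:
        hits, remnants, n_orfs, n_long, orf_table = [], [], 0, 0, []
    log.info("IS: %d families, %d hits, %d distinct sites",
             len(families), len(hits), len(remnants))
    for r in remnants:
        called.add(genome_io.Feature(
            r.site_id, r.replicon_id, r.start, r.end, r.strand, "IS_remnant",
            attrs={"family": r.family_id, "status": r.status,
                   "n_fragments": len(r.fragments),
                   "tir_found": str(r.tir_found).lower()}))

    summary = stage("stats")(erosion_stats.erosion_summary, genome, called)

    chisq = None
    cog_table = None
    try:
        cog_table = cog_enrichment.build_table(called)
        chisq = stage("cog")(cog_enrichment.simulated_pvalue, cog_table,
                             cfg.enrichment_B, cfg.seed)
    except cog_enrichment.DegenerateTableError as exc:
        log.warning("COG enrichment skipped: %s", exc)

    geneset_block = None
    if cfg.gene_set_tsv and cfg.gene_set_fasta:
        entries = geneset_compare.load_gene_set(
            cfg.gene_set_tsv, cfg.gene_set_fasta, cfg.gene_set_name)
        statuses = stage("geneset")(
            geneset_compare.classify_gene_set, entries, genome, called,
            caller_cfg)
        geneset_compare.write_status_tsv(statuses, outdir / "geneset_status.tsv")
        geneset_block = [asdict(s) for s in statuses]

    manifest = genome_io.write_outputs(called, summary, outdir,
                                       cog_table, chisq)
    report.update({
        "erosion": {
            "per_replicon": summary.per_replicon,
            "genome_totals": summary.genome_totals,
            "coding_fraction_percent": summary.coding_fraction_percent,
            "pseudogene_percent_of_genes": summary.pseudogene_percent_of_genes,
        },
        "pseudogene_fraction": summary.pseudogene_percent_of_genes / 100.0,
        "per_replicon": summary.per_replicon,
        "chisq": chisq.to_dict() if chisq else None,
        "is_census": {
            "n_families": len(families),
            "n_hits": len(hits),
            "n_distinct_sites": len(remnants),
            "n_raw_fragments": sum(len(r.fragments) for r in remnants),
            "n_transposase_orfs": n_orfs,
            "n_long_transposase_orfs": n_long,
        },
        "geneset": geneset_block,
        "manifest": manifest,
    })
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["digests"] = {
        name: _sha256(outdir / name)
        for name in ("calls.gff3", "erosion.tsv", "cog_table.tsv", "report.json")
        if (outdir / name).exists()
    }
    return report
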