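"""End-to-end orchestration: simulate -> expression -> DE -> hotspot scan
-> ORA -> hormones, from one YAML config with a single root seed.

Every stage writes its outputs as plain-text TSV/BED so any stage can be
re-run from saved intermediates; reruns with the same (config, seed) are
byte-identical. A machine-readable manifest (config echo, package
version) is written next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexp, expression, hormones, io, ora, posenrich
from .errors import ChillseqError, InvalidConfigError
from .simulate import (
    SimConfig,
    generate_annotation,
    generate_counts,
    generate_hormone_panel,
    generate_qtl_bed,
    generate_term_annotation,
)

log = logging.getLogger("chillseq")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class PipelineConfig:
    """Everything one run needs: either a simulation block or input paths,
    plus the per-stage parameters."""

    outdir: str = "chillseq_out"
    seed: int = 0
    simulate: SimConfig | None = None
    # external inputs, used when no simulation block is present
    annotation_bed: str | None = None
    counts_tsv: str | None = None
    design_tsv: str | None = None
    hormone_tsv: str | None = None
    qtl_bed: str | None = None
    term_tsv: str | None = None
    # stage parameters
    detect_threshold: float = expression.DEFAULT_DETECT_FPKM
    detect_min_replicates: int = expression.DEFAULT_DETECT_MIN_REPLICATES
    r2_min: float = expression.DEFAULT_R2_MIN
    fc_min: float = diffexp.DEFAULT_FC_MIN
    fdr_max: float = diffexp.DEFAULT_FDR_MAX
    bin_size: int = posenrich.DEFAULT_BIN_SIZE
    index_threshold: float = posenrich.DEFAULT_INDEX_THRESHOLD
    min_degs: int = posenrich.DEFAULT_MIN_DEGS
    max_gap_bins: int = posenrich.DEFAULT_MAX_GAP_BINS
    t_variant: str = hormones.DEFAULT_VARIANT
    alpha: float = hormones.DEFAULT_ALPHA
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 50)
    enriched_terms: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("TERM:HOT", 20, 0.8)]
    )
    verbose: bool = False

    def validate(self) -> None:
        if self.simulate is None:
            needed = [self.annotation_bed, self.counts_tsv, self.design_tsv]
            if any(p is None for p in needed):
                raise InvalidConfigError(
                    "config needs either a simulate block or annotation/counts/design paths"
                )
            for p in needed + [self.hormone_tsv, self.qtl_bed, self.term_tsv]:
                if p is not None and not Path(p).exists():
                    raise InvalidConfigError(f"input file not found: {p}")
        if not (0 < self.fdr_max <= 1) or self.fc_min < 1:
            raise InvalidConfigError("fc_min must be >=1 and fdr_max in (0,1]")
        if self.bin_size <= 0:
            raise InvalidConfigError("bin_size must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimConfig.from_dict(raw["simulate"])
        if "term_size_range" in raw:
            raw["term_size_range"] = tuple(raw["term_size_range"])
        if "enriched_terms" in raw:
            raw["enriched_terms"] = [tuple(t) for t in raw["enriched_terms"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["term_size_range"] = list(self.term_size_range)
        d["enriched_terms"] = [list(t) for t in self.enriched_terms]
        return d


def _timed(name):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _T()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # -- inputs (simulated or loaded) --------------------------------------
    truth = None
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed
        with _timed("simulate"):
            annotation = generate_annotation(sim)
            cm, truth = generate_counts(annotation, sim)
            hormone_table = generate_hormone_panel(sim)
            io.write_annotation_bed(annotation, out / "annotation.bed")
            io.write_annotation_gff3(annotation, out / "annotation.gff3")
            io.write_counts(cm, out / "counts.tsv", out / "design.tsv")
            io.write_tsv(hormone_table, out / "hormones.tsv")
            io.write_sim_config(sim, out / "sim_config.yaml")
            truth_df = pd.DataFrame(
                {
                    "gene_id": truth.true_log2fc.index,
                    "true_log2fc": truth.true_log2fc.to_numpy(),
                    "is_de": [g in truth.de_gene_ids for g in truth.true_log2fc.index],
                }
            )
            io.write_tsv(truth_df, out / "ground_truth.tsv")
            qtls = generate_qtl_bed(
                [(c, s, e, f"hot_region_{i + 1}") for i, (c, s, e, _f) in enumerate(sim.hot_regions)]
            )
    else:
        annotation = io.read_annotation_bed(config.annotation_bed)
        cm = io.read_counts(config.counts_tsv, config.design_tsv)
        hormone_table = io.read_tsv(config.hormone_tsv) if config.hormone_tsv else None
        if config.qtl_bed:
            raw = io.read_bed(config.qtl_bed)
            qtls = generate_qtl_bed(
                [tuple(r) for r in raw[["chrom", "start", "end", "name"]].itertuples(index=False)]
            )
        else:
            qtls = generate_qtl_bed([])
    io.write_bed(qtls, out / "qtl.bed")

    # -- expression ---------------------------------------------------------
    with _timed("expression"):
        expr = expression.compute_fpkm(cm, annotation.lengths)
        io.write_tsv(expr.values, out / "fpkm.tsv", index=True)
        qc = expression.replicate_qc(expr, cm.design, r2_min=config.r2_min)
        io.write_tsv(qc.r2, out / "qc_r2.tsv", index=True)
        io.write_tsv(qc.pca, out / "qc_pca.tsv", index=True)
        summary["flagged_replicate_pairs"] = len(qc.flagged_pairs)

        tissues = list(dict.fromkeys(cm.design["tissue"]))
        detected: dict[str, set[str]] = {}
        for t in tissues:
            detected[t] = expression.detect_genes(
                expr, cm.samples_for(tissue=t),
                threshold=config.detect_threshold,
                min_replicates=config.detect_min_replicates,
            )
            summary[f"detected_{t}"] = len(detected[t])
        if len(tissues) >= 2:
            a_only, b_only, shared = expression.tissue_specific(
                detected[tissues[0]], detected[tissues[1]]
            )
            summary[f"{tissues[0]}_specific"] = len(a_only)
            summary[f"{tissues[1]}_specific"] = len(b_only)
            summary["shared_detected"] = len(shared)

    # -- differential expression -------------------------------------------
    genotypes = list(dict.fromkeys(cm.design["genotype"]))
    if len(genotypes) != 2:
        raise ChillseqError(f"pipeline expects two genotypes, got {genotypes}")
    deg_union: set[str] = set()
    de_tables: dict[str, pd.DataFrame] = {}
    with _timed("diffexp"):
        for t in tissues:
            res = diffexp.nb_test(cm, genotypes=(genotypes[0], genotypes[1]), tissue=t)
            res = diffexp.call_degs(res, fc_min=config.fc_min, fdr_max=config.fdr_max)
            de_tables[t] = res
            io.write_tsv(res.reset_index(names="gene_id"), out / f"de_{t}.tsv")
            degs = diffexp.deg_set(res)
            deg_union |= degs
            summary[f"degs_{t}"] = len(degs)

    # -- positional enrichment scan ------------------------------------------
    with _timed("scan"):
        bins = posenrich.bin_genome(annotation, bin_size=config.bin_size)
        if deg_union:
            bins = posenrich.enrichment_index(bins, deg_union, annotation)
            regions = posenrich.call_enriched_regions(
                bins, threshold=config.index_threshold,
                min_degs=config.min_degs, max_gap_bins=config.max_gap_bins,
            )
            regions = posenrich.overlap_qtl(
                regions, qtls, known_chroms=set(annotation.chrom_lengths)
            )
        else:
            log.warning("no DEGs called; skipping enrichment scan")
            regions = []
        if "index" in bins:
            io.write_bedgraph(bins, out / "enrichment_track.bedgraph")
        rt = posenrich.regions_table(regions)
        io.write_tsv(rt, out / "enriched_regions.tsv")
        summary["enriched_regions"] = len(regions)
        summary["regions_overlapping_qtl"] = sum(1 for r in regions if r.qtl_names)
        for r in regions:
            genes = posenrich.genes_in_region(annotation, r.chrom, r.start, r.end)
            io.write_tsv(genes, out / f"region_genes_{r.chrom}_{r.start}.tsv")

    # -- over-representation --------------------------------------------------
    with _timed("ora"):
        if config.term_tsv:
            terms = ora.read_term_annotation(config.term_tsv)
        elif truth is not None:
            terms = generate_term_annotation(
                annotation, n_terms=config.n_terms,
                size_range=config.term_size_range,
                enriched_terms=config.enriched_terms,
                seed=config.seed, de_genes=truth.de_gene_ids,
            )
            ora.write_term_annotation(terms, out / "terms.tsv")
        else:
            terms = {}
        if terms and deg_union:
            universe = set(annotation.gene_ids)
            enrich = ora.hypergeom_enrich(deg_union & universe, universe, terms)
            io.write_tsv(enrich, out / "ora.tsv")
            summary["significant_terms"] = int((enrich["padj"] < config.alpha).sum())

    # -- hormones ---------------------------------------------------------------
    with _timed("hormones"):
        if hormone_table is not None:
            panel = hormones.summarize_panel(
                hormone_table, alpha=config.alpha, variant=config.t_variant
            )
            io.write_tsv(hormones.format_report(panel), out / "hormone_report.tsv")
            summary["significant_hormones"] = int(panel["significant"].sum())

    # -- manifest -----------------------------------------------------------------
    cfg_dict = config.to_dict()
    manifest = {
        "package": "chillseq",
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
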