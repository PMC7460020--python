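"""End-to-end pipeline: filter -> ROH -> summaries -> islands -> inbreeding
-> F_ST -> PCA, with a manifest and deterministic table output."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotype_io import (
    GenotypeMatrix,
    GroupAssignment,
    MarkerMap,
    filter_call_rate,
    read_groups,
    read_ped_map,
    restrict_chromosomes,
)
from .inbreeding import FrohConfig, excess_hom_f, f_roh, hom_het_summary, regress_f_froh
from .popgen import allele_freqs, monomorphic_counts, pairwise_fst, pca
from .roh import ROHParams, detect_roh, write_roh_bed, write_roh_tsv
from .rohstats import (
    LengthClassConfig,
    annotate_islands,
    chromosome_summary,
    classify_lengths,
    find_islands,
    read_gene_intervals,
    snp_incidence,
    summarize_per_group,
    summarize_per_sample,
    write_islands_bed,
    write_islands_tsv,
)

log = logging.getLogger("rohscan")

#: exit-code contract used by the CLI
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    ped: str
    map: str
    groups: str
    out_dir: str
    genes: str | None = None
    min_call_rate: float = 0.99
    chromosomes: list[str] | None = None
    min_snps: int = 150
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 0
    class_boundaries_mb: list[float] = field(default_factory=lambda: [0.0, 2.0, 4.0, 8.0])
    island_threshold: float = 0.70
    island_min_snps: int = 2
    froh_denominator_bp: int | None = None
    fst_estimator: str = "weir-cockerham"
    pca_components: int = 10
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def roh_params(self) -> ROHParams:
        return ROHParams(self.min_snps, self.min_length_bp, self.max_gap_bp,
                         self.max_het, self.max_missing)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep="NA")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all tables; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "inputs": {},
        "tables": [],
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            manifest["stages"].append(name)
            return result
        return deco

    def table(name, writer):
        writer(out / name)
        manifest["tables"].append(name)

    @stage("load")
    def loaded():
        gm, mmap = read_ped_map(cfg.ped, cfg.map)
        groups = read_groups(cfg.groups)
        groups.indices(gm.sample_ids)  # validate
        for key, p in (("ped", cfg.ped), ("map", cfg.map), ("groups", cfg.groups)):
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
        if cfg.genes:
            manifest["inputs"]["genes"] = {"path": str(cfg.genes), "sha256": _sha256(cfg.genes)}
        return gm, mmap, groups

    gm, mmap, groups = loaded
    manifest["n_markers_input"] = len(mmap)
    manifest["n_samples"] = gm.n_samples

    @stage("filter")
    def filtered():
        g2, m2 = filter_call_rate(gm, mmap, cfg.min_call_rate)
        if cfg.chromosomes:
            g2, m2 = restrict_chromosomes(g2, m2, cfg.chromosomes)
        return g2, m2

    gm_f, mmap_f = filtered
    manifest["n_markers_filtered"] = len(mmap_f)

    params = cfg.roh_params()
    classes = LengthClassConfig(tuple(cfg.class_boundaries_mb))

    @stage("roh")
    def rohs():
        return detect_roh(gm_f, mmap_f, params)

    records = rohs
    manifest["n_roh"] = len(records)
    table("roh.tsv", lambda p: write_roh_tsv(records, p))
    table("roh.bed", lambda p: write_roh_bed(records, p))

    @stage("summaries")
    def _summaries():
        table("sample_summary.tsv",
              lambda p: _write(summarize_per_sample(records, gm_f.sample_ids), p))
        table("group_summary.tsv",
              lambda p: _write(summarize_per_group(records, groups, gm_f.sample_ids), p))
        counts, pct = classify_lengths(records, groups, classes)
        table("length_class_counts.tsv", lambda p: _write(counts, p))
        table("length_class_pct.tsv", lambda p: _write(pct, p))
        table("chromosome_summary.tsv",
              lambda p: _write(chromosome_summary(records, mmap_f.chromosomes), p))

    _summaries

    @stage("islands")
    def islands_out():
        profile = snp_incidence(records, mmap_f, groups)
        islands = find_islands(profile, cfg.island_threshold, cfg.island_min_snps)
        gene_lists = None
        if cfg.genes:
            genes = read_gene_intervals(cfg.genes)
            gene_lists = annotate_islands(islands, genes)
        table("islands.tsv", lambda p: write_islands_tsv(islands, p, gene_lists))
        table("islands.bed", lambda p: write_islands_bed(islands, p))
        return islands

    islands_out

    @stage("inbreeding")
    def inb():
        freqs = allele_freqs(gm_f)
        fdf = excess_hom_f(gm_f, freqs)
        froh = f_roh(records, mmap_f, gm_f.sample_ids,
                     FrohConfig(cfg.froh_denominator_bp), classes)
        per_sample = fdf.join(froh.total).join(froh.per_class)
        table("inbreeding.tsv", lambda p: _write(per_sample.round(6), p))
        table("froh_by_chromosome.tsv", lambda p: _write(froh.per_chromosome.round(6), p))
        table("hom_het.tsv", lambda p: _write(hom_het_summary(gm_f, groups).round(3), p))
        reg = regress_f_froh(fdf["F"], froh.total, groups)
        table("f_vs_froh_regression.tsv", lambda p: _write(reg.round(4), p))
        # group-level report mirroring a descriptive inbreeding table
        rows = []
        for g in groups.labels:
            members = groups.samples_in(g)
            rows.append((g,
                         float(fdf.loc[members, "F"].mean()),
                         float(fdf.loc[members, "F"].std(ddof=1)),
                         float(froh.total.loc[members].mean()),
                         float(froh.total.loc[members].std(ddof=1))))
        gdf = pd.DataFrame(rows, columns=["group", "F_mean", "F_sd",
                                          "froh_mean", "froh_sd"]).set_index("group")
        table("inbreeding_groups.tsv", lambda p: _write(gdf.round(3), p))
        return fdf, froh

    inb

    @stage("fst")
    def fst_out():
        res = pairwise_fst(gm_f, groups, cfg.fst_estimator)
        table("fst.tsv", lambda p: _write(res.summary(), p))
        raw = pd.DataFrame(
            [(a, b, v) for (a, b), v in res.estimates.items()],
            columns=["group1", "group2", "fst_raw"],
        )
        table("fst_audit.tsv", lambda p: _write(raw.round(6), p, index=False))
        return res

    fst_out

    @stage("pca")
    def pca_out():
        res = pca(gm_f, cfg.pca_components)
        scores = pd.DataFrame(
            res.scores, index=pd.Index(gm_f.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])],
        )
        scores["group"] = [groups.mapping.get(s, "NA") for s in gm_f.sample_ids]
        table("pca_scores.tsv", lambda p: _write(scores.round(6), p))
        eig = pd.DataFrame({"eigenvalue": np.round(res.eigenvalues, 6)},
                           index=[f"PC{i + 1}" for i in range(len(res.eigenvalues))])
        table("pca_eigenvalues.tsv", lambda p: _write(eig, p))
        return res

    pca_out

    @stage("monomorphic")
    def mono():
        table("monomorphic_counts.tsv",
              lambda p: _write(monomorphic_counts(gm_f, mmap_f, groups), p))

    mono

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
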