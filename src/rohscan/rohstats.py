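"""Summaries of detected ROH: per sample / chromosome / length class,
SNP-in-ROH incidence per group, island calling and gene annotation.

Length classes are half-open ``[a, b)`` in Mb, so a run of exactly 2.000 Mb
falls in class 2-4 and the classes partition (0, inf).  An overflow class
``[8, inf)`` always exists.  Islands are maximal stretches of consecutive
markers whose ROH incidence within a group meets the threshold (inclusive,
"at least 70%"); the island interval runs from the first to the last
qualifying marker.  Interval overlap is computed on closed 1-based
[start, end] coordinates; BED exports convert to 0-based half-open.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import GroupAssignment, MarkerMap, natural_chrom_key
from .roh import ROHRecord


@dataclass(frozen=True)
class LengthClassConfig:
    """Half-open length classes in Mb; boundaries must start at 0."""

    boundaries_mb: tuple = (0.0, 2.0, 4.0, 8.0)

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries_mb)
        if b[0] != 0.0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must start at 0 and be strictly increasing")
        object.__setattr__(self, "boundaries_mb", b)

    @property
    def boundaries_bp(self) -> np.ndarray:
        return np.asarray([int(round(x * 1e6)) for x in self.boundaries_mb])

    @property
    def labels(self) -> list[str]:
        b = self.boundaries_mb

        def fmt(x):
            return f"{x:g}"

        out = [f"{fmt(a)}-{fmt(c)} Mb" for a, c in zip(b[:-1], b[1:])]
        out.append(f">={fmt(b[-1])} Mb")
        return out

    def class_index(self, length_bp) -> np.ndarray:
        """Index of the half-open class containing each length."""
        return np.searchsorted(self.boundaries_bp, np.asarray(length_bp), side="right") - 1


@dataclass
class IncidenceProfile:
    """Per group, per marker: fraction of samples with a ROH covering it."""

    mmap: MarkerMap
    counts: dict[str, np.ndarray]  # group -> int counts per marker
    sizes: dict[str, int]

    def incidence(self, group: str) -> np.ndarray:
        return self.counts[group] / self.sizes[group]


@dataclass(frozen=True)
class IslandRecord:
    """Group-level high-incidence ROH region (first..last qualifying SNP)."""

    group: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    min_incidence: float
    mean_incidence: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class GeneInterval:
    """Gene on closed 1-based [start_bp, end_bp] coordinates."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError(f"gene {self.name}: end must exceed start")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_per_sample(records: Iterable[ROHRecord],
                         sample_ids: Sequence[str]) -> pd.DataFrame:
    """Per-sample ROH count and length stats; zero-ROH samples kept with NA."""
    lengths: dict[str, list[int]] = {s: [] for s in sample_ids}
    for r in records:
        lengths[r.sample_id].append(r.length_bp)
    rows = []
    for s in sample_ids:
        ls = np.asarray(lengths[s], dtype=float)
        if len(ls):
            rows.append((s, len(ls), ls.sum(), ls.mean() / 1e6, ls.min() / 1e6, ls.max() / 1e6))
        else:
            rows.append((s, 0, 0.0, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "n_roh", "total_length_bp", "mean_length_mb",
                 "min_length_mb", "max_length_mb"],
    ).set_index("sample_id")


def summarize_per_group(records: Sequence[ROHRecord], groups: GroupAssignment,
                        sample_ids: Sequence[str]) -> pd.DataFrame:
    """Group-level analogue of a descriptive ROH table: ranges and means."""
    per_sample = summarize_per_sample(records, sample_ids)
    rows = []
    for g in groups.labels:
        members = [s for s in sample_ids if groups.mapping.get(s) == g]
        sub = per_sample.loc[members]
        ls = np.asarray([r.length_bp for r in records if groups.mapping.get(r.sample_id) == g],
                        dtype=float)
        rows.append(
            (
                g,
                len(members),
                int(sub["n_roh"].sum()),
                int(sub["n_roh"].min()),
                int(sub["n_roh"].max()),
                float(sub["n_roh"].mean()),
                float(ls.min() / 1e6) if len(ls) else np.nan,
                float(ls.max() / 1e6) if len(ls) else np.nan,
                float(ls.mean() / 1e6) if len(ls) else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_samples", "n_roh", "min_n_roh", "max_n_roh",
                 "mean_n_roh", "min_length_mb", "max_length_mb", "mean_length_mb"],
    ).set_index("group")


def classify_lengths(records: Sequence[ROHRecord], groups: GroupAssignment,
                     cfg: LengthClassConfig = LengthClassConfig()
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group length-class counts and integer-rounded percentages."""
    labels = cfg.labels
    counts = pd.DataFrame(0, index=groups.labels, columns=labels, dtype=int)
    for r in records:
        g = groups.mapping.get(r.sample_id)
        if g is None:
            continue
        counts.loc[g, labels[int(cfg.class_index(r.length_bp))]] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    pct_int = pct.round(0).astype("Int64")
    return counts, pct_int


def chromosome_summary(records: Sequence[ROHRecord],
                       chromosomes: Sequence[str]) -> pd.DataFrame:
    """Count and mean length (Mb) per chromosome; zero-ROH chromosomes kept."""
    by: dict[str, list[int]] = {c: [] for c in chromosomes}
    for r in records:
        if r.chromosome in by:
            by[r.chromosome].append(r.length_bp)
    rows = [
        (c, len(v), float(np.mean(v)) / 1e6 if v else np.nan)
        for c, v in by.items()
    ]
    return pd.DataFrame(rows, columns=["chromosome", "n_roh", "mean_length_mb"]
                        ).set_index("chromosome")


# ---------------------------------------------------------------------------
# Incidence and islands
# ---------------------------------------------------------------------------

def snp_incidence(records: Sequence[ROHRecord], mmap: MarkerMap,
                  groups: GroupAssignment) -> IncidenceProfile:
    """Fraction of each group's samples whose ROH cover each marker.

    A marker is covered iff ``start_bp <= position <= end_bp`` of any ROH of
    that sample.  The denominator is the full group size, including samples
    without any ROH.
    """
    m = len(mmap)
    slices = mmap.chrom_slices()
    per_sample: dict[str, np.ndarray] = {}
    for r in records:
        cov = per_sample.get(r.sample_id)
        if cov is None:
            cov = per_sample[r.sample_id] = np.zeros(m, dtype=bool)
        sl = slices[r.chromosome]
        pos = mmap.position_bp[sl]
        i0 = int(np.searchsorted(pos, r.start_bp, side="left"))
        i1 = int(np.searchsorted(pos, r.end_bp, side="right"))
        cov[sl.start + i0: sl.start + i1] = True
    counts: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for g in groups.labels:
        members = groups.samples_in(g)
        if not members:
            raise ValueError(f"group {g} has no samples")
        acc = np.zeros(m, dtype=np.int64)
        for s in members:
            if s in per_sample:
                acc += per_sample[s]
        counts[g] = acc
        sizes[g] = len(members)
    return IncidenceProfile(mmap, counts, sizes)


def find_islands(profile: IncidenceProfile, threshold: float = 0.70,
                 min_snps: int = 2) -> list[IslandRecord]:
    """Maximal stretches of consecutive markers with incidence >= threshold.

    Comparison is inclusive ("at least 70%") and evaluated on integer counts
    to avoid float boundary artifacts.  Stretches with fewer than ``min_snps``
    markers are dropped (a single-marker island has zero length).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    mmap = profile.mmap
    out: list[IslandRecord] = []
    for g, cnt in profile.counts.items():
        size = profile.sizes[g]
        qual = cnt >= threshold * size - 1e-9
        inc = cnt / size
        for chrom, sl in mmap.chrom_slices().items():
            q = qual[sl]
            pos = mmap.position_bp[sl]
            i = 0
            n = len(q)
            while i < n:
                if not q[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < n and q[j + 1]:
                    j += 1
                if j - i + 1 >= min_snps:
                    window = inc[sl][i: j + 1]
                    out.append(
                        IslandRecord(g, chrom, int(pos[i]), int(pos[j]),
                                     j - i + 1, float(window.min()),
                                     float(window.mean()))
                    )
                i = j + 1
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_intervals(path, fmt: str | None = None,
                        feature_types: Sequence[str] = ("gene",),
                        name_keys: Sequence[str] = ("Name", "gene", "gene_name", "ID"),
                        ) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    BED starts are converted to 1-based closed coordinates.  For GFF3, only
    records whose feature type is in ``feature_types`` are kept and the gene
    name is taken from the first attribute key present in ``name_keys``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    genes: list[GeneInterval] = []
    if fmt == "bed":
        with open(path) as fh:
            for line in fh:
                tok = line.split()
                if not tok or tok[0].startswith(("#", "track", "browser")):
                    continue
                name = tok[3] if len(tok) > 3 else f"{tok[0]}:{tok[1]}-{tok[2]}"
                genes.append(GeneInterval(name, tok[0], int(tok[1]) + 1, int(tok[2])))
    elif fmt == "gff3":
        from gffutils.feature import feature_from_line

        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = feature_from_line(line)
                if f.featuretype not in feature_types:
                    continue
                name = next(
                    (f.attributes[k][0] for k in name_keys if k in f.attributes),
                    f"{f.seqid}:{f.start}-{f.end}",
                )
                genes.append(GeneInterval(name, f.seqid, f.start, f.end))
    else:
        raise ValueError(f"unknown gene file format: {fmt}")
    return genes


def annotate_islands(islands: Sequence[IslandRecord],
                     genes: Sequence[GeneInterval]) -> list[list[GeneInterval]]:
    """Genes overlapping each island by >= 1 bp on closed intervals.

    Returns one gene list per island, sorted by gene start.  Islands on
    chromosomes absent from the gene set get an empty list with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    out: list[list[GeneInterval]] = []
    warned: set[str] = set()
    for isl in islands:
        tree = trees.get(isl.chromosome)
        if tree is None:
            if genes and isl.chromosome not in warned:
                warnings.warn(
                    f"no gene intervals on chromosome {isl.chromosome}", stacklevel=2
                )
                warned.add(isl.chromosome)
            out.append([])
            continue
        hits = [iv.data for iv in tree.overlap(isl.start_bp, isl.end_bp + 1)]
        out.append(sorted(hits, key=lambda g: (g.start_bp, g.name)))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def islands_to_frame(islands: Sequence[IslandRecord],
                     gene_lists: Sequence[Sequence[GeneInterval]] | None = None
                     ) -> pd.DataFrame:
    rows = []
    for k, isl in enumerate(islands):
        genes = ""
        if gene_lists is not None:
            genes = ",".join(g.name for g in gene_lists[k])
        rows.append(
            (isl.group, isl.chromosome, isl.start_bp, isl.end_bp, isl.length_bp,
             isl.n_snps, round(isl.min_incidence, 4), round(isl.mean_incidence, 4),
             genes)
        )
    return pd.DataFrame(
        rows,
        columns=["group", "chromosome", "start_bp", "end_bp", "length_bp",
                 "n_snps", "min_incidence", "mean_incidence", "genes"],
    )


def write_islands_tsv(islands: Sequence[IslandRecord], path,
                      gene_lists=None) -> None:
    islands_to_frame(islands, gene_lists).to_csv(path, sep="\t", index=False)


def write_islands_bed(islands: Sequence[IslandRecord], path) -> None:
    """BED export: 0-based half-open, i.e. (start_bp - 1, end_bp)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(
                f"{isl.chromosome}\t{isl.start_bp - 1}\t{isl.end_bp}\t{isl.group}\t{isl.n_snps}\n"
            )
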