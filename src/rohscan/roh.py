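"""Runs of homozygosity: the consecutive (scan) method and a brute-force oracle.

The consecutive method walks each sample's markers in map order per
chromosome, without sliding windows.  A candidate run is a maximal stretch of
consecutive markers containing at most ``max_het`` heterozygous and
``max_missing`` missing calls, with every adjacent-marker gap at most
``max_gap_bp`` (a larger gap always terminates a run).  A candidate is
emitted iff it contains at least ``min_snps`` homozygous markers and spans at
least ``min_length_bp``, where the span is end position minus start position.

With the default ``max_het = max_missing = 0`` maximal runs are unique and
disjoint.  For positive tolerances the scan emits maximal windows
left-to-right and drops windows fully contained in an emitted one; the
brute-force oracle implements the same containment rule, and the test suite
asserts their equivalence on randomized instances.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    _check_aligned,
)


@dataclass(frozen=True)
class ROHParams:
    """Constraint set of the consecutive method.

    Defaults are the common SNP-array settings for medium-density data:
    at least 150 homozygous SNPs spanning at least 1 Mb, no heterozygous and
    no missing call inside a run, and no adjacent-marker gap above 1 Mb (so
    sparse marker coverage cannot fake a long run).
    """

    min_snps: int = 150
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_het: int = 0
    max_missing: int = 0

    def __post_init__(self):
        if min(self.min_snps, self.max_gap_bp, self.max_het, self.max_missing) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass(frozen=True)
class ROHRecord:
    """One homozygous run; ``length_bp`` uses the end - start convention."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int  # homozygous markers inside the run

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def overlaps(self, other: "ROHRecord") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def _scan_strict(g: np.ndarray, pos: np.ndarray, params: ROHParams
                 ) -> list[tuple[int, int, int]]:
    """Fast path for max_het = max_missing = 0: vectorized segment scan."""
    hom = (g == 0) | (g == 2)
    if not hom.any():
        return []
    cut = np.empty(len(pos), dtype=bool)
    cut[0] = True
    cut[1:] = np.diff(pos) > params.max_gap_bp
    prev_hom = np.concatenate(([False], hom[:-1]))
    next_hom = np.concatenate((hom[1:], [False]))
    cut_next = np.concatenate((cut[1:], [True]))
    starts = np.flatnonzero(hom & (~prev_hom | cut))
    ends = np.flatnonzero(hom & (~next_hom | cut_next))
    out = []
    for s, e in zip(starts, ends):
        n = int(e - s + 1)
        if n >= params.min_snps and pos[e] - pos[s] >= params.min_length_bp:
            out.append((int(s), int(e), n))
    return out


def _scan_tolerant(g: np.ndarray, pos: np.ndarray, params: ROHParams
                   ) -> list[tuple[int, int, int]]:
    """General two-pointer scan emitting maximal windows left-to-right."""
    m = len(pos)
    het = np.concatenate(([0], np.cumsum(g == 1)))
    mis = np.concatenate(([0], np.cumsum(g == MISSING)))
    hom = np.concatenate(([0], np.cumsum((g == 0) | (g == 2))))
    cut = np.flatnonzero(np.diff(pos) > params.max_gap_bp)  # gap after index i
    seg_bounds = [0, *[c + 1 for c in cut], m]
    out = []
    for lo, hi in zip(seg_bounds[:-1], seg_bounds[1:]):
        hi -= 1  # inclusive
        j = lo - 1
        prev_j = lo - 2
        for i in range(lo, hi + 1):
            if j < i - 1:
                j = i - 1
            while (
                j + 1 <= hi
                and het[j + 2] - het[i] <= params.max_het
                and mis[j + 2] - mis[i] <= params.max_missing
            ):
                j += 1
            if j >= i and (i == lo or j > prev_j):
                n = int(hom[j + 1] - hom[i])
                if n >= params.min_snps and pos[j] - pos[i] >= params.min_length_bp:
                    out.append((i, j, n))
            prev_j = j
    return out


def detect_roh(gm: GenotypeMatrix, mmap: MarkerMap,
               params: ROHParams = ROHParams()) -> list[ROHRecord]:
    """Detect ROH per sample per chromosome with the consecutive method.

    Records are returned in (sample order, natural chromosome order, start)
    order.  Runs never span chromosomes; an empty matrix yields an empty list.
    """
    _check_aligned(gm, mmap)
    strict = params.max_het == 0 and params.max_missing == 0
    slices = mmap.chrom_slices()
    records: list[ROHRecord] = []
    for si, sid in enumerate(gm.sample_ids):
        row = gm.calls[si]
        for chrom, sl in slices.items():
            g = row[sl]
            pos = mmap.position_bp[sl]
            runs = _scan_strict(g, pos, params) if strict else _scan_tolerant(g, pos, params)
            for i, j, n in runs:
                records.append(
                    ROHRecord(sid, chrom, int(pos[i]), int(pos[j]), n)
                )
    return records


def detect_roh_oracle(gm: GenotypeMatrix, mmap: MarkerMap,
                      params: ROHParams = ROHParams(),
                      max_cells: int = 10_000) -> list[ROHRecord]:
    """Exhaustive window enumeration; reference oracle for small instances.

    Enumerates every marker window per sample/chromosome, keeps windows
    satisfying all five constraints, then discards windows strictly contained
    in a larger valid window.  Refuses instances above ``max_cells``
    sample x marker cells.
    """
    _check_aligned(gm, mmap)
    if gm.n_samples * gm.n_markers > max_cells:
        raise ValueError(
            f"oracle instance too large: {gm.n_samples * gm.n_markers} cells > {max_cells}"
        )
    records: list[ROHRecord] = []
    for si, sid in enumerate(gm.sample_ids):
        row = gm.calls[si]
        for chrom, sl in mmap.chrom_slices().items():
            g = row[sl]
            pos = mmap.position_bp[sl]
            m = len(pos)
            het = np.concatenate(([0], np.cumsum(g == 1)))
            mis = np.concatenate(([0], np.cumsum(g == MISSING)))
            hom = np.concatenate(([0], np.cumsum((g == 0) | (g == 2))))
            # furthest index reachable from i without an over-large gap
            reach = np.empty(m, dtype=np.intp)
            r = m - 1
            for i in range(m - 1, -1, -1):
                if i < m - 1 and pos[i + 1] - pos[i] > params.max_gap_bp:
                    r = i
                reach[i] = r
            valid = []
            for i in range(m):
                for j in range(i, reach[i] + 1):
                    if het[j + 1] - het[i] > params.max_het:
                        continue
                    if mis[j + 1] - mis[i] > params.max_missing:
                        continue
                    if hom[j + 1] - hom[i] < params.min_snps:
                        continue
                    if pos[j] - pos[i] < params.min_length_bp:
                        continue
                    valid.append((i, j))
            kept = [
                (i, j)
                for (i, j) in valid
                if not any(
                    (i2 <= i and j <= j2 and (i2, j2) != (i, j)) for (i2, j2) in valid
                )
            ]
            for i, j in sorted(kept):
                records.append(
                    ROHRecord(sid, chrom, int(pos[i]), int(pos[j]),
                              int(hom[j + 1] - hom[i]))
                )
    return records


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def roh_to_frame(records: Iterable[ROHRecord]) -> pd.DataFrame:
    rows = [
        (r.sample_id, r.chromosome, r.start_bp, r.end_bp, r.n_snps, r.length_bp)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]
    )


def write_roh_tsv(records: Sequence[ROHRecord], path) -> None:
    roh_to_frame(records).to_csv(path, sep="\t", index=False)


def write_roh_bed(records: Sequence[ROHRecord], path) -> None:
    """BED export: 0-based half-open, i.e. (start_bp - 1, end_bp)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{r.sample_id}\t{r.n_snps}\n"
            )
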