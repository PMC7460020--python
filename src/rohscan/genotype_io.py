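"""Genotype and marker-map containers, PLINK text I/O and marker filters.

Genotypes are stored as diploid allele counts of a per-marker *counted*
allele: 0, 1 or 2, with :data:`MISSING` (-1) for a missing call.  The counted
allele is the lexicographically larger of the two allele symbols observed at
the marker, which makes the recoding deterministic without a reference
genome; every downstream statistic in this package is symmetric under
swapping allele labels, so the arbitrary polarity is harmless.

Coordinates are 1-based base pairs, as in a PLINK MAP file.  Marker maps are
always kept sorted by (chromosome, position) with chromosome labels ordered
naturally (``"2" < "10" < "Z"``).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call.  Never a valid allele count.
MISSING = -1


class PedParseError(ValueError):
    """Malformed PED/MAP content (ragged line, bad allele column, ...)."""


class DimensionMismatchError(ValueError):
    """PED and MAP disagree on the number of markers, or matrix/map misalign."""


_NAT_TOKEN = re.compile(r"(\d+)")


def natural_chrom_key(label) -> tuple:
    """Sort key ordering chromosome labels numerically where possible.

    ``"1" < "2" < "10" < "30" < "Z"``; purely lexicographic comparison would
    put "10" before "2".
    """
    return tuple(
        (0, int(tok)) if tok.isdigit() else (1, tok)
        for tok in _NAT_TOKEN.split(str(label))
        if tok != ""
    )


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map: id, chromosome label, 1-based bp position.

    Invariants enforced at construction: unique marker ids, chromosome blocks
    contiguous in natural order, positions strictly increasing within a
    chromosome.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray([str(c) for c in self.chromosome], dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(mid) == len(chrom) == len(pos)):
            raise DimensionMismatchError("marker map columns differ in length")
        if len(np.unique(mid)) != len(mid):
            raise ValueError("duplicate marker_id in map")
        if len(pos) and pos.min() < 1:
            raise ValueError("positions must be >= 1 (1-based bp)")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)
        self._check_sorted()

    def _check_sorted(self):
        keys = [natural_chrom_key(c) for c in self.chromosome]
        seen = {}
        prev_key = None
        for i, k in enumerate(keys):
            if k != prev_key:
                if k in seen:
                    raise ValueError("chromosome blocks are not contiguous; map unsorted")
                if prev_key is not None and k < prev_key:
                    raise ValueError("chromosomes out of natural order; map unsorted")
                seen[k] = i
                prev_key = k
            elif self.position_bp[i] <= self.position_bp[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on chromosome "
                    f"{self.chromosome[i]} near {self.position_bp[i]}"
                )

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map (natural) order."""
        out, prev = [], None
        for c in self.chromosome:
            if c != prev:
                out.append(c)
                prev = c
        return out

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice of every chromosome."""
        out: dict[str, slice] = {}
        start, prev = 0, None
        for i, c in enumerate(self.chromosome):
            if c != prev:
                if prev is not None:
                    out[prev] = slice(start, i)
                start, prev = i, c
        if prev is not None:
            out[prev] = slice(start, len(self.chromosome))
        return out

    def chrom_spans(self) -> dict[str, int]:
        """max position - min position per chromosome (bp covered by markers)."""
        return {
            c: int(self.position_bp[sl][-1] - self.position_bp[sl][0])
            for c, sl in self.chrom_slices().items()
        }

    def take(self, index) -> "MarkerMap":
        index = np.asarray(index)
        return MarkerMap(self.marker_id[index], self.chromosome[index], self.position_bp[index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )

    @staticmethod
    def sorted_order(chromosome, position_bp) -> np.ndarray:
        """Stable permutation sorting markers by (natural chromosome, bp)."""
        keys = [natural_chrom_key(c) for c in chromosome]
        pos = np.asarray(position_bp)
        return np.array(
            sorted(range(len(pos)), key=lambda i: (keys[i], pos[i])), dtype=np.intp
        )


@dataclass
class GenotypeMatrix:
    """samples x markers allele-count matrix aligned to a :class:`MarkerMap`."""

    sample_ids: list[str]
    calls: np.ndarray  # int8, values in {0,1,2,MISSING}

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        calls = np.asarray(self.calls)
        if calls.ndim != 2:
            raise DimensionMismatchError("calls must be 2-D (samples x markers)")
        if calls.shape[0] != len(self.sample_ids):
            raise DimensionMismatchError("row count != number of sample ids")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid call values: {np.unique(calls[bad])}")
        self.calls = calls.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def _check_aligned(gm: GenotypeMatrix, mmap: MarkerMap) -> None:
    if gm.n_markers != len(mmap):
        raise DimensionMismatchError(
            f"matrix has {gm.n_markers} markers but map has {len(mmap)}"
        )


@dataclass
class GroupAssignment:
    """sample_id -> group label mapping with ordered group helpers."""

    mapping: dict[str, str]

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.mapping:
            raise ValueError("empty group assignment")

    @property
    def labels(self) -> list[str]:
        out, seen = [], set()
        for g in self.mapping.values():
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == label]

    def indices(self, sample_ids: Sequence[str]) -> dict[str, np.ndarray]:
        """Per-group row indices into ``sample_ids`` (insertion order)."""
        lookup = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in self.mapping if s not in lookup]
        if missing:
            raise ValueError(f"grouped samples absent from matrix: {missing[:5]}")
        return {
            g: np.array([lookup[s] for s in self.samples_in(g)], dtype=np.intp)
            for g in self.labels
        }

    def group_of(self, sample_id: str) -> str:
        return self.mapping[sample_id]


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw MAP columns (chrom, id, bp) in file order; 4 columns required."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise PedParseError(
                    f"{map_path}: line {lineno}: expected 4 MAP columns, got {len(tok)}"
                )
            rows.append((tok[0], tok[1], int(tok[3])))
    chrom = np.array([r[0] for r in rows], dtype=object)
    mid = np.array([r[1] for r in rows], dtype=object)
    pos = np.array([r[2] for r in rows], dtype=np.int64)
    return chrom, mid, pos


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK text PED/MAP into an allele-count matrix and a sorted map.

    Allele pairs are recoded per marker to counts of the lexicographically
    larger observed allele; ``0`` alleles mark a missing call (a half-missing
    pair is treated as fully missing, as PLINK does).  Markers are sorted by
    (natural chromosome, position) and matrix columns permuted accordingly.
    """
    chrom, mid, pos = read_map(map_path)
    m = len(mid)
    sample_ids: list[str] = []
    a1_rows, a2_rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6 or (len(tok) - 6) % 2:
                raise PedParseError(f"{ped_path}: line {lineno}: ragged PED line")
            if (len(tok) - 6) // 2 != m:
                raise DimensionMismatchError(
                    f"{ped_path}: line {lineno}: {(len(tok) - 6) // 2} genotypes "
                    f"but MAP lists {m} markers"
                )
            sample_ids.append(tok[1])
            alleles = np.array(tok[6:], dtype=object)
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])
    if not sample_ids:
        raise PedParseError(f"{ped_path}: no samples")
    a1 = np.vstack(a1_rows)
    a2 = np.vstack(a2_rows)

    calls = np.empty((len(sample_ids), m), dtype=np.int8)
    for j in range(m):
        c1, c2 = a1[:, j], a2[:, j]
        miss = (c1 == "0") | (c2 == "0")
        observed = sorted(set(c1[~miss]) | set(c2[~miss]))
        if len(observed) > 2:
            raise PedParseError(
                f"marker {mid[j]}: more than two alleles observed: {observed}"
            )
        counted = observed[-1] if observed else "0"
        calls[:, j] = (c1 == counted).astype(np.int8) + (c2 == counted).astype(np.int8)
        calls[miss, j] = MISSING

    order = MarkerMap.sorted_order(chrom, pos)
    mmap = MarkerMap(mid[order], chrom[order], pos[order])
    return GenotypeMatrix(sample_ids, calls[:, order]), mmap


def write_ped_map(gm: GenotypeMatrix, mmap: MarkerMap, ped_path, map_path,
                  family_id: str = "FAM") -> None:
    """Write PLINK text files; counted allele written as ``B``, the other ``A``.

    ``B`` sorts after ``A``, so :func:`read_ped_map` recovers the calls
    exactly for every marker at which the counted allele is observed at least
    once (see package notes on the all-0 monomorphic corner case).
    """
    _check_aligned(gm, mmap)
    pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            geno = " ".join(pair[int(c)] for c in gm.calls[i])
            fh.write(f"{family_id} {sid} 0 0 0 -9 {geno}\n")
    with open(map_path, "w") as fh:
        for c, m, p in zip(mmap.chromosome, mmap.marker_id, mmap.position_bp):
            fh.write(f"{c} {m} 0 {p}\n")


def read_groups(path) -> GroupAssignment:
    """TSV with columns (sample_id, group); a header line is auto-detected."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.rstrip("\n").split("\t")
            if not tok or tok == [""]:
                continue
            if len(tok) != 2:
                raise PedParseError(f"{path}: line {lineno}: expected 2 TSV columns")
            if lineno == 1 and tok[0].lower() in ("sample_id", "sample", "id"):
                continue
            mapping[tok[0]] = tok[1]
    return GroupAssignment(mapping)


def write_groups(groups: GroupAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in groups.mapping.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Marker filters
# ---------------------------------------------------------------------------

def filter_call_rate(gm: GenotypeMatrix, mmap: MarkerMap, min_rate: float
                     ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Keep markers whose non-missing fraction across samples >= ``min_rate``.

    Marker order is preserved; the comparison tolerates float representation
    of rates such as 0.99.  Idempotent.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    _check_aligned(gm, mmap)
    rate = (gm.calls != MISSING).mean(axis=0)
    keep = rate >= min_rate - 1e-12
    if not keep.any():
        warnings.warn("call-rate filter removed every marker", stacklevel=2)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(gm.sample_ids, gm.calls[:, idx]), mmap.take(idx)


def restrict_chromosomes(gm: GenotypeMatrix, mmap: MarkerMap,
                         chrom_set: Iterable) -> tuple[GenotypeMatrix, MarkerMap]:
    """Keep only markers on the listed chromosomes."""
    wanted = {str(c) for c in chrom_set}
    if not wanted:
        raise ValueError("chrom_set must be non-empty")
    present = set(mmap.chromosomes)
    unknown = sorted(wanted - present, key=natural_chrom_key)
    if unknown:
        raise ValueError(f"unknown chromosome labels: {unknown} (map has {sorted(present, key=natural_chrom_key)})")
    _check_aligned(gm, mmap)
    keep = np.array([c in wanted for c in mmap.chromosome])
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(gm.sample_ids, gm.calls[:, idx]), mmap.take(idx)
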