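"""Population structure statistics: allele frequencies, pairwise F_ST,
principal components, and monomorphic-marker counts.

F_ST uses the Weir & Cockerham (1984) variance-component estimator with
ratio-of-sums aggregation across markers (sum of among-population components
over sum of total components), the standard multi-locus form.  A Hudson-type
estimator (Bhatia et al. 2013 formulation) is available for sensitivity
checks.  Negative per-pair estimates are kept as computed in the audit output
and truncated at zero in the summary table.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    GroupAssignment,
    MarkerMap,
    natural_chrom_key,
)


@dataclass
class AlleleFreqTable:
    """Per-marker frequency of the counted allele over a stated sample set.

    ``p`` is NaN at markers where every sample in the reference set is
    missing; such markers are excluded downstream.
    """

    p: np.ndarray
    n_obs: np.ndarray  # non-missing samples per marker

    def __len__(self) -> int:
        return len(self.p)


def allele_freqs(gm: GenotypeMatrix, sample_indices=None) -> AlleleFreqTable:
    """p = (counted-allele copies) / (2 x non-missing samples) per marker."""
    calls = gm.calls if sample_indices is None else gm.calls[np.asarray(sample_indices)]
    if calls.shape[0] == 0:
        raise ValueError("empty sample subset")
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0)
    cnt = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, cnt / (2.0 * n), np.nan)
    return AlleleFreqTable(p.astype(float), n.astype(np.int64))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Pairwise F_ST with per-marker variance components kept for audit."""

    labels: list[str]
    estimates: dict[tuple[str, str], float]
    components: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def get(self, g1: str, g2: str) -> float:
        if g1 == g2:
            return 0.0
        key = tuple(sorted((g1, g2)))
        return self.estimates[key]

    def summary(self, decimals: int = 3) -> pd.DataFrame:
        """Symmetric matrix, negatives truncated at 0, rounded for report."""
        mat = pd.DataFrame(0.0, index=self.labels, columns=self.labels)
        for (a, b), v in self.estimates.items():
            val = round(max(float(v), 0.0), decimals) if np.isfinite(v) else np.nan
            mat.loc[a, b] = mat.loc[b, a] = val
        return mat


def _wc_components(calls1: np.ndarray, calls2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) a, b, c per marker for two populations."""
    comps = []
    for calls in (calls1, calls2):
        nonmiss = calls != MISSING
        n = nonmiss.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n)
            h = (np.where(nonmiss, calls, 0) == 1).sum(axis=0) / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    informative = (
        (n1 >= 2) & (n2 >= 2)
        & np.isfinite(p1) & np.isfinite(p2)
        & ~((p1 == p2) & ((p1 == 0.0) | (p1 == 1.0)))  # monomorphic across both
    )
    return a, b, c, informative


def _hudson_fst(calls1: np.ndarray, calls2: np.ndarray) -> float:
    out = []
    for calls in (calls1, calls2):
        nonmiss = calls != MISSING
        n = 2.0 * nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nonmiss, calls, 0).sum(axis=0) / n
        out.append((n, p))
    (n1, p1), (n2, p2) = out
    ok = (n1 >= 4) & (n2 >= 4) & np.isfinite(p1) & np.isfinite(p2)
    ok &= ~((p1 == p2) & ((p1 == 0.0) | (p1 == 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    if not ok.any() or den[ok].sum() == 0:
        return np.nan
    return float(num[ok].sum() / den[ok].sum())


def pairwise_fst(gm: GenotypeMatrix, groups: GroupAssignment,
                 estimator: str = "weir-cockerham") -> FstResult:
    """Pairwise F_ST between all group pairs; ratio-of-sums across markers.

    Markers monomorphic across both groups of a pair, or observed in fewer
    than two samples of either group, are skipped for that pair.
    """
    idx = groups.indices(gm.sample_ids)
    for g, rows in idx.items():
        if len(rows) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    estimates: dict[tuple[str, str], float] = {}
    components: dict[tuple[str, str], pd.DataFrame] = {}
    for g1, g2 in itertools.combinations(groups.labels, 2):
        key = tuple(sorted((g1, g2)))
        c1, c2 = gm.calls[idx[g1]], gm.calls[idx[g2]]
        if estimator == "weir-cockerham":
            a, b, c, ok = _wc_components(c1, c2)
            if not ok.any():
                warnings.warn(f"no informative markers for pair {key}", stacklevel=2)
                estimates[key] = np.nan
                continue
            denom = (a + b + c)[ok].sum()
            estimates[key] = float(a[ok].sum() / denom) if denom != 0 else np.nan
            components[key] = pd.DataFrame(
                {"a": a[ok], "b": b[ok], "c": c[ok]},
                index=np.flatnonzero(ok),
            )
        elif estimator == "hudson":
            estimates[key] = _hudson_fst(c1, c2)
        else:
            raise ValueError(f"unknown estimator: {estimator}")
    return FstResult(groups.labels, estimates, components)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray       # samples x components
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray     # markers x components
    marker_index: np.ndarray  # columns of the input matrix actually used


def pca(gm: GenotypeMatrix, n_components: int = 10, scale: bool = False) -> PcaResult:
    """PCA of the genotype matrix (samples in rows).

    Markers with undefined frequency are excluded and missing calls are
    mean-imputed per marker.  Columns are centered on 2p; with
    ``scale=True`` they are additionally divided by sqrt(2 p (1-p)).
    Deterministic up to sign; the sign is fixed by making each component's
    largest-magnitude loading positive.
    """
    freqs = allele_freqs(gm)
    keep = np.isfinite(freqs.p)
    if scale:
        keep &= (freqs.p > 0) & (freqs.p < 1)
    cols = np.flatnonzero(keep)
    X = gm.calls[:, cols].astype(float)
    p = freqs.p[cols]
    mean = 2.0 * p
    X[gm.calls[:, cols] == MISSING] = np.nan
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    X -= mean
    if scale:
        X /= np.sqrt(2.0 * p * (1.0 - p))
    n = X.shape[0]
    if n < 2:
        return PcaResult(np.zeros((n, 0)), np.zeros(0), np.zeros((len(cols), 0)), cols)
    X -= X.mean(axis=0)  # exact column centering (finite-sample means)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if len(S) else 0.0
    rank = int((S > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1.0
            U[:, comp] *= -1.0
    eigenvalues = S ** 2 / (n - 1)
    return PcaResult(U * S, eigenvalues, Vt.T, cols)


# ---------------------------------------------------------------------------
# Monomorphic markers
# ---------------------------------------------------------------------------

def monomorphic_counts(gm: GenotypeMatrix, mmap: MarkerMap,
                       groups: GroupAssignment,
                       by_chromosome: bool = True) -> pd.DataFrame | pd.Series:
    """Markers with within-group frequency in {0, 1} (missing calls ignored).

    Markers with no observed call in a group are not counted.
    """
    idx = groups.indices(gm.sample_ids)
    mono = {}
    for g, rows in idx.items():
        f = allele_freqs(gm, rows)
        mono[g] = np.isfinite(f.p) & ((f.p == 0.0) | (f.p == 1.0))
    if not by_chromosome:
        return pd.Series({g: int(v.sum()) for g, v in mono.items()}, name="n_monomorphic")
    chroms = mmap.chromosomes
    out = pd.DataFrame(0, index=chroms, columns=list(mono), dtype=int)
    for chrom, sl in mmap.chrom_slices().items():
        for g, v in mono.items():
            out.loc[chrom, g] = int(v[sl].sum())
    out.index.name = "chromosome"
    return out
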