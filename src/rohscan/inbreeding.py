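"""Genomic inbreeding coefficients.

Two estimators are provided:

* ``F`` (excess homozygosity): per sample,
  ``F = (O_hom - E_hom) / (L - E_hom)`` where ``O_hom`` is the observed
  number of homozygous genotypes over the sample's non-missing markers,
  ``E_hom = sum_i (1 - 2 p_i (1 - p_i))`` is the Hardy-Weinberg expectation
  at the reference allele frequencies, and ``L`` is the number of markers
  used.  Negative values indicate a heterozygote excess, the signature of a
  hybrid cross of unrelated inbred lines.  Frequencies default to the full
  input cohort; within-group frequencies can be supplied explicitly.  An
  optional finite-sample correction (2 p q n/(n-1)) is available but off by
  default.

* ``F_ROH``: total ROH length of a sample divided by the genome length
  covered by markers.  The denominator defaults to the sum over chromosomes
  of (max marker position - min marker position) and can be overridden by a
  constant (e.g. an assembly's published autosomal coverage).  Per-class
  variants restrict the numerator only, so class values sum exactly to the
  total; per-chromosome variants use per-chromosome marker spans as
  denominators.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, GroupAssignment, MarkerMap
from .popgen import AlleleFreqTable, allele_freqs
from .roh import ROHRecord
from .rohstats import LengthClassConfig


@dataclass(frozen=True)
class FrohConfig:
    """F_ROH denominator; ``None`` derives it from the marker map."""

    denominator_bp: int | None = None

    def __post_init__(self):
        if self.denominator_bp is not None and self.denominator_bp <= 0:
            raise ValueError("denominator_bp must be positive")

    def resolve(self, mmap: MarkerMap) -> tuple[int, dict[str, int]]:
        spans = mmap.chrom_spans()
        total = self.denominator_bp if self.denominator_bp is not None else sum(spans.values())
        return int(total), spans


@dataclass
class FrohResult:
    total: pd.Series                   # per sample
    per_class: pd.DataFrame            # samples x class labels
    per_chromosome: pd.DataFrame       # samples x chromosomes
    class_length_bp: pd.DataFrame      # integer numerators per class
    denominator_bp: int
    chrom_denominators: dict[str, int]


def excess_hom_f(gm: GenotypeMatrix, freqs: AlleleFreqTable | None = None,
                 sample_size_correction: bool = False) -> pd.DataFrame:
    """Per-sample excess-homozygosity F with O_hom, E_hom and L columns.

    Markers with undefined frequency are excluded; monomorphic markers
    contribute an expectation of 1 homozygote and cancel from both numerator
    and denominator.  If the denominator ``L - E_hom`` vanishes, F is NA.
    """
    if freqs is None:
        freqs = allele_freqs(gm)
    if len(freqs) != gm.n_markers:
        raise ValueError("frequency table not aligned to matrix")
    p = freqs.p
    valid = np.isfinite(p)
    exp_het = 2.0 * p * (1.0 - p)
    if sample_size_correction:
        n = freqs.n_obs.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_het = np.where(n > 1, exp_het * n / (n - 1.0), exp_het)
    e = 1.0 - exp_het
    use = (gm.calls != MISSING) & valid[None, :]
    hom = ((gm.calls == 0) | (gm.calls == 2)) & use
    L = use.sum(axis=1).astype(float)
    O = hom.sum(axis=1).astype(float)
    E = use @ np.where(valid, e, 0.0)
    denom = L - E
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    if np.isnan(F).any():
        warnings.warn("F undefined for some samples (L - E_hom = 0)", stacklevel=2)
    return pd.DataFrame(
        {"F": F, "O_hom": O.astype(int), "E_hom": E, "L": L.astype(int)},
        index=pd.Index(gm.sample_ids, name="sample_id"),
    )


def f_roh(records: Sequence[ROHRecord], mmap: MarkerMap,
          sample_ids: Sequence[str],
          cfg: FrohConfig = FrohConfig(),
          classes: LengthClassConfig = LengthClassConfig()) -> FrohResult:
    """Per-sample F_ROH: total, per length class, per chromosome."""
    denominator, spans = cfg.resolve(mmap)
    labels = classes.labels
    chroms = mmap.chromosomes
    class_len = pd.DataFrame(0, index=list(sample_ids), columns=labels, dtype=np.int64)
    chrom_len = pd.DataFrame(0, index=list(sample_ids), columns=chroms, dtype=np.int64)
    for r in records:
        if r.sample_id not in class_len.index:
            continue
        lab = labels[int(classes.class_index(r.length_bp))]
        class_len.loc[r.sample_id, lab] += r.length_bp
        chrom_len.loc[r.sample_id, r.chromosome] += r.length_bp
    total = class_len.sum(axis=1) / denominator
    total.name = "froh_total"
    per_class = class_len / denominator
    chrom_denoms = pd.Series({c: spans[c] for c in chroms}, dtype=float)
    per_chrom = chrom_len / chrom_denoms
    return FrohResult(total, per_class, per_chrom, class_len, denominator, dict(spans))


def hom_het_summary(gm: GenotypeMatrix, groups: GroupAssignment,
                    freqs: AlleleFreqTable | None = None) -> pd.DataFrame:
    """Per-group observed/expected homozygosity and heterozygosity (%).

    Observed values are means over samples of per-sample genotype fractions;
    expected values come from Hardy-Weinberg proportions at within-group
    allele frequencies unless an explicit frequency table is given.
    """
    idx = groups.indices(gm.sample_ids)
    rows = []
    for g, ridx in idx.items():
        calls = gm.calls[ridx]
        nonmiss = calls != MISSING
        L = nonmiss.sum(axis=1).astype(float)
        obs_hom = (((calls == 0) | (calls == 2)).sum(axis=1) / L * 100.0).mean()
        obs_het = ((calls == 1).sum(axis=1) / L * 100.0).mean()
        f = freqs if freqs is not None else allele_freqs(gm, ridx)
        p = f.p[np.isfinite(f.p)]
        exp_het = float(np.mean(2.0 * p * (1.0 - p)) * 100.0)
        rows.append((g, obs_hom, 100.0 - exp_het, obs_het, exp_het))
    return pd.DataFrame(
        rows, columns=["group", "obs_hom_pct", "exp_hom_pct", "obs_het_pct", "exp_het_pct"]
    ).set_index("group")


def regress_f_froh(f: pd.Series, froh: pd.Series,
                   groups: GroupAssignment) -> pd.DataFrame:
    """Per-group OLS of F (y) on F_ROH (x) with R^2.

    With zero variance in F_ROH the slope is undefined (NA); R^2 is then 0
    when F still varies (a constant predictor explains nothing) and NA when
    both are constant.
    """
    rows = []
    for g in groups.labels:
        members = [s for s in groups.samples_in(g) if s in f.index and s in froh.index]
        x = froh.loc[members].astype(float)
        y = f.loc[members].astype(float)
        ok = x.notna() & y.notna()
        x, y = x[ok].to_numpy(), y[ok].to_numpy()
        if len(x) < 3:
            rows.append((g, np.nan, np.nan, np.nan, len(x)))
            continue
        if np.ptp(x) == 0.0:
            r2 = 0.0 if np.ptp(y) > 0 else np.nan
            rows.append((g, np.nan, float(np.mean(y)), r2, len(x)))
            continue
        res = stats.linregress(x, y)
        rows.append((g, res.slope, res.intercept, res.rvalue ** 2, len(x)))
    return pd.DataFrame(
        rows, columns=["group", "slope", "intercept", "r_squared", "n"]
    ).set_index("group")
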