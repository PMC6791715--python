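"""Developmental vs constitutive gene calling, and its permutation FDR.

A gene is *developmentally regulated* when, over the starvation time course,

1. every per-replicate, per-time count is at least ``min_reads`` (50),
2. the two replicate RPKM trajectories agree (squared Pearson correlation
   r² > ``min_r2`` = 0.7), and
3. the replicate-merged RPKM trajectory spans more than ``min_fold`` (2×)
   between its maximum and minimum.

Genes failing (1) are ``filtered_low`` (or ``filtered_missing`` when a cell
is absent altogether), genes failing (2) are ``filtered_discordant``, and
genes passing (1)+(2) but not (3) are ``constitutive``.

The procedure's false discovery rate is estimated by *time scrambling*:
independently permuting the order of the time points within each replicate
dataset (one permutation per replicate per simulation, shared across genes)
and re-running the caller.  Identical permutations in both replicates would
leave both r² and the fold change untouched; only independent per-replicate
scrambles perturb the replicate-concordance criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DesignError, UndefinedStatisticError
from .quantify import ExpressionTable

CLASSES = ("developmental", "constitutive", "filtered_low",
           "filtered_discordant", "filtered_missing")


@dataclass
class RegulationThresholds:
    """The calling criteria: <50-read filter, r² > 0.7, fold > 2.

    ``fold_floor`` is a pseudocount for the trajectory minimum; the default 0
    means a zero minimum yields an infinite fold change (developmental).
    ``low_filter`` is ``per_replicate`` (strict; each replicate count must
    reach min_reads) or ``pooled`` (replicate-summed counts per time point).
    """

    min_reads: int = 50
    min_r2: float = 0.7
    min_fold: float = 2.0
    fold_floor: float = 0.0
    low_filter: str = "per_replicate"

    def __post_init__(self):
        if self.min_reads < 0 or not (0 <= self.min_r2 <= 1) or self.min_fold < 1:
            raise ValueError("thresholds out of range")
        if self.low_filter not in ("per_replicate", "pooled"):
            raise ValueError(f"unknown low_filter {self.low_filter!r}")


def _call_tensors(counts: np.ndarray, rpkm: np.ndarray, merged: np.ndarray,
                  thr: RegulationThresholds):
    """Vectorized caller on genes × times × replicates tensors.

    Returns (class codes into CLASSES, gene_r2, fold_change); r2/fold are NaN
    for filtered genes where the corresponding quantity was never reached.
    """
    g, t, r = counts.shape
    if t < 3:
        raise DesignError("developmental calling needs >= 3 time points")
    if r != 2:
        raise DesignError("replicate concordance r2 is defined for 2 replicates")

    missing = np.isnan(counts).any(axis=(1, 2)) | np.isnan(rpkm).any(axis=(1, 2))
    if thr.low_filter == "per_replicate":
        low = np.nan_to_num(counts, nan=np.inf).min(axis=(1, 2)) < thr.min_reads
    else:
        low = np.nan_to_num(counts, nan=np.inf).sum(axis=2).min(axis=1) < thr.min_reads
    low &= ~missing

    a, b = rpkm[:, :, 0], rpkm[:, :, 1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    den = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = ((ac * bc).sum(axis=1) / den) ** 2
    zero_var = (den == 0) & ~missing & ~low
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} gene(s) with a zero-variance replicate "
            "trajectory: r2 undefined, classified filtered_discordant",
            stacklevel=3,
        )
    discordant = (~missing & ~low) & (zero_var | ~(r2 > thr.min_r2))

    mx = merged.max(axis=1)
    mn = merged.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = mx / np.maximum(mn, thr.fold_floor)
    evaluated = ~missing & ~low & ~discordant
    developmental = evaluated & (fold > thr.min_fold)
    constitutive = evaluated & ~developmental

    codes = np.full(g, 4, dtype=int)  # filtered_missing
    codes[low] = 2
    codes[discordant] = 3
    codes[constitutive] = 1
    codes[developmental] = 0

    r2_out = np.where(missing | low | zero_var, np.nan, r2)
    fold_out = np.where(evaluated, fold, np.nan)
    return codes, r2_out, fold_out


class DevelopmentalGeneCaller(BaseEstimator):
    """Threshold classifier for developmental regulation.

    Parameters mirror :class:`RegulationThresholds`.  ``fit`` takes an
    :class:`~tempomod.quantify.ExpressionTable` (which carries the aligned
    count tensor) and exposes the per-gene calls in ``calls_``.
    """

    def __init__(self, min_reads: int = 50, min_r2: float = 0.7,
                 min_fold: float = 2.0, fold_floor: float = 0.0,
                 low_filter: str = "per_replicate"):
        self.min_reads = min_reads
        self.min_r2 = min_r2
        self.min_fold = min_fold
        self.fold_floor = fold_floor
        self.low_filter = low_filter

    def _thresholds(self) -> RegulationThresholds:
        return RegulationThresholds(self.min_reads, self.min_r2, self.min_fold,
                                    self.fold_floor, self.low_filter)

    def fit(self, et: ExpressionTable, y=None):
        thr = self._thresholds()
        counts, rpkm = et.to_tensors()
        codes, r2, fold = _call_tensors(counts, rpkm,
                                        et.rpkm_merged.to_numpy(float), thr)
        self.calls_ = pd.DataFrame(
            {"class": pd.Categorical.from_codes(codes, categories=list(CLASSES)),
             "gene_r2": r2, "fold_change": fold},
            index=et.genes.rename("gene_id"),
        )
        self.class_counts_ = self.calls_["class"].value_counts().to_dict()
        self.n_developmental_ = int(self.class_counts_["developmental"])
        return self

    def developmental_genes_(self) -> pd.Index:
        return self.calls_.index[self.calls_["class"] == "developmental"]


def call_regulation(et: ExpressionTable,
                    thresholds: RegulationThresholds | None = None) -> pd.DataFrame:
    """Per-gene regulation calls (class, gene_r2, fold_change)."""
    thr = thresholds or RegulationThresholds()
    caller = DevelopmentalGeneCaller(**vars(thr))
    return caller.fit(et).calls_


@dataclass
class FdrEstimate:
    """Time-scrambling FDR: 100 · mean(scrambled passes) / observed passes."""

    n_sims: int
    observed_pass: int
    scrambled_pass_per_sim: list[int]
    fdr_pct: float
    seed: int


def scramble_fdr(et: ExpressionTable,
                 thresholds: RegulationThresholds | None = None,
                 n_sims: int = 5, seed: int = 0) -> FdrEstimate:
    """Estimate the caller's FDR by scrambling time points per replicate.

    Each simulation draws one uniform permutation of the time points per
    replicate dataset (independent between replicates), applies it to all
    genes' counts and RPKM values within that replicate, recomputes the
    merged trajectories, and re-runs the caller.
    """
    thr = thresholds or RegulationThresholds()
    counts, rpkm = et.to_tensors()
    merged = et.rpkm_merged.to_numpy(float)
    obs_codes, _, _ = _call_tensors(counts, rpkm, merged, thr)
    observed = int((obs_codes == 0).sum())
    if observed == 0:
        raise UndefinedStatisticError("no observed developmental genes: FDR undefined")

    rng = np.random.default_rng(seed)
    t = counts.shape[1]
    passes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sims):
            sc, sr = counts.copy(), rpkm.copy()
            for rep in range(counts.shape[2]):
                perm = rng.permutation(t)
                sc[:, :, rep] = counts[:, perm, rep]
                sr[:, :, rep] = rpkm[:, perm, rep]
            sm = sr.mean(axis=2)
            codes, _, _ = _call_tensors(sc, sr, sm, thr)
            passes.append(int((codes == 0).sum()))
    fdr = 100.0 * float(np.mean(passes)) / observed
    return FdrEstimate(n_sims=n_sims, observed_pass=observed,
                       scrambled_pass_per_sim=passes, fdr_pct=fdr, seed=seed)
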