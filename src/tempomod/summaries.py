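"""Dataset-level descriptive statistics: tallies and mRNA breadth.

The breadth statistic asks how concentrated the transcriptome is at a time
point: the minimal number of top-expressed genes whose cumulative RPKM
reaches a given fraction (default 50%) of the time point's total.  A small
number means a few transcripts dominate the mRNA pool (typical of fast
growth); the number rises as expression spreads across more genes late in
development.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .errors import UndefinedStatisticError
from .quantify import ExpressionTable


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100·numerator/denominator, rounded half-up to *ndigits* decimals."""
    if denominator == 0:
        raise UndefinedStatisticError("percentage undefined: zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class BreadthResult:
    time_h: float
    n_genes_50pct: int
    fraction: float = 0.5


def breadth50(et: ExpressionTable | pd.DataFrame, time_h,
              fraction: float = 0.5) -> BreadthResult:
    """Minimal number of top genes reaching *fraction* of total RPKM.

    Merged RPKM values are sorted descending (ties broken by gene_id for
    determinism) and scanned until the cumulative sum first reaches
    fraction·total (closed threshold, >=).  With fraction=1 this returns the
    number of genes with nonzero RPKM.
    """
    merged = et.rpkm_merged if isinstance(et, ExpressionTable) else et
    col = merged[time_h]
    total = float(col.sum())
    if total <= 0:
        raise UndefinedStatisticError(f"total RPKM at {time_h} h is zero")
    ordered = col.sort_index().sort_values(ascending=False, kind="stable")
    cum = np.cumsum(ordered.to_numpy(float))
    n = int(np.searchsorted(cum, fraction * total - 1e-9 * total) + 1)
    return BreadthResult(time_h=time_h, n_genes_50pct=n, fraction=fraction)


def breadth_profile(et: ExpressionTable, fraction: float = 0.5) -> pd.DataFrame:
    """Breadth statistic at every time point of the table."""
    rows = [vars(breadth50(et, t, fraction)) for t in et.times_h]
    return pd.DataFrame(rows)[["time_h", "n_genes_50pct"]]


def tally_report(calls: pd.DataFrame, dgs: pd.DataFrame | None,
                 total_genes: int,
                 subsets: dict[str, list] | None = None) -> pd.DataFrame:
    """Headline tallies as (metric, numerator, denominator, pct) rows.

    Covers: filter-passing genes over the genome, constitutive and
    developmental shares of the passing set, the developmental share of the
    genome, per-DG and per-phase shares of the developmental set, and any
    extra named gene subsets measured against the developmental set.
    """
    if total_genes <= 0:
        raise UndefinedStatisticError("total_genes must be positive")
    n_dev = int((calls["class"] == "developmental").sum())
    n_con = int((calls["class"] == "constitutive").sum())
    n_pass = n_dev + n_con
    rows = [
        ("passed_filters_of_total", n_pass, total_genes),
        ("constitutive_of_passed", n_con, n_pass),
        ("developmental_of_passed", n_dev, n_pass),
        ("developmental_of_total", n_dev, total_genes),
    ]
    if dgs is not None and len(dgs):
        for dg, cnt in dgs["dg"].value_counts().sort_index().items():
            rows.append((f"dg{dg}_of_developmental", int(cnt), len(dgs)))
        if dgs["phase"].notna().all():
            for phase, cnt in dgs["phase"].value_counts().items():
                rows.append((f"{phase}_of_developmental", int(cnt), len(dgs)))
    dev_genes = set(calls.index[calls["class"] == "developmental"])
    for name, genes in (subsets or {}).items():
        rows.append((f"{name}_of_developmental",
                     len(dev_genes & set(genes)), n_dev))
    out = pd.DataFrame(rows, columns=["metric", "numerator", "denominator"])
    out["pct"] = [percent(n, d) for n, d in zip(out["numerator"], out["denominator"])]
    return out


def sequencing_summary(sheet: pd.DataFrame, read_len_bp: int = 100,
                       genome_len_bp: int | None = None) -> dict:
    """Run-level sequencing statistics across all samples.

    Mean mapped reads in millions (two decimals), mean rRNA rate, and when a
    genome length is supplied the min/max clean-read genome coverage.
    """
    from .quantify import sample_stats

    stats = sample_stats(sheet, read_len_bp=read_len_bp, genome_len_bp=genome_len_bp)
    out = {
        "n_samples": int(len(sheet)),
        "mean_mapped_reads_millions": round_half_up(
            float(sheet["mapped_reads"].mean()) / 1e6, 2),
        "mean_rrna_rate_pct": round_half_up(float(stats["rrna_rate_pct"].mean()), 2),
    }
    if genome_len_bp is not None:
        out["min_coverage_x"] = float(stats["coverage_x"].min())
        out["max_coverage_x"] = float(stats["coverage_x"].max())
    return out
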