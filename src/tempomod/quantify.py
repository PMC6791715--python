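"""Per-sample summary statistics and RPKM expression tables.

RPKM (reads per kilobase of transcript per million mapped reads) is computed
with an rRNA-excluded library size: the default library size of a sample is
its *clean* read count (mapped minus rRNA reads), because in a bacterial
total-RNA library the overwhelming majority (~98%) of reads are ribosomal
and would otherwise dominate the normalization.

    rpkm = reads * 1e9 / (length_bp * library_size)

Replicates are merged per time point by the arithmetic mean of the replicate
RPKMs (for a two-replicate design the mean and median coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .errors import DesignError, UndefinedStatisticError, ValidationError


def sample_stats(sheet: pd.DataFrame, read_len_bp: int = 100,
                 genome_len_bp: int | None = None) -> pd.DataFrame:
    """Sequencing summary per sample.

    Returns a frame indexed by sample_id with ``clean_reads`` (mapped − rRNA),
    ``rrna_rate_pct`` (two decimals) and, when *genome_len_bp* is given,
    ``coverage_x`` = clean_reads·read_len_bp/genome_len_bp (two decimals).
    """
    if (sheet["mapped_reads"] == 0).any():
        sid = sheet.loc[sheet["mapped_reads"] == 0, "sample_id"].iloc[0]
        raise UndefinedStatisticError(f"rRNA rate undefined: mapped_reads=0 for {sid}")
    out = pd.DataFrame(index=pd.Index(sheet["sample_id"], name="sample_id"))
    clean = (sheet["mapped_reads"] - sheet["rrna_reads"]).to_numpy()
    out["clean_reads"] = clean
    rate = 100.0 * sheet["rrna_reads"].to_numpy() / sheet["mapped_reads"].to_numpy()
    out["rrna_rate_pct"] = [round_half_up(v, 2) for v in rate]
    if genome_len_bp is not None:
        if genome_len_bp <= 0 or read_len_bp <= 0:
            raise ValidationError("read_len_bp and genome_len_bp must be positive")
        cov = clean * float(read_len_bp) / float(genome_len_bp)
        out["coverage_x"] = [round_half_up(v, 2) for v in cov]
    return out


def rpkm(reads, length_bp, library_size):
    """RPKM of a gene: reads·10⁹/(length_bp·library_size).  Vectorized."""
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_bp <= 0):
        raise ValidationError("length_bp must be positive")
    if np.any(library_size <= 0):
        raise ValidationError("library_size must be positive")
    out = np.asarray(reads, dtype=float) * 1e9 / (length_bp * library_size)
    return out if out.ndim else float(out)


@dataclass
class ExpressionTable:
    """RPKM per gene per (time, replicate) plus the replicate-merged matrix.

    ``counts`` and ``rpkm_rep`` share a column MultiIndex (time_h, replicate)
    sorted by time then replicate; ``rpkm_merged`` has one column per time.
    ``library_sizes`` is indexed like the replicate columns.
    """

    counts: pd.DataFrame
    rpkm_rep: pd.DataFrame
    rpkm_merged: pd.DataFrame
    library_sizes: pd.Series
    lengths_bp: pd.Series = field(repr=False, default=None)

    @property
    def genes(self) -> pd.Index:
        return self.rpkm_merged.index

    @property
    def times_h(self) -> list:
        return list(self.rpkm_merged.columns)

    @property
    def replicates(self) -> list:
        return sorted(self.rpkm_rep.columns.get_level_values("replicate").unique())

    def to_tensors(self):
        """(counts, rpkm) as genes × times × replicates float arrays."""
        g, t, r = len(self.genes), len(self.times_h), len(self.replicates)
        return (self.counts.to_numpy(float).reshape(g, t, r),
                self.rpkm_rep.to_numpy(float).reshape(g, t, r))


def counts_by_condition(cm: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Re-key count columns from sample_id to a (time_h, replicate) MultiIndex."""
    meta = sheet.set_index("sample_id")
    missing = [s for s in cm.columns if s not in meta.index]
    if missing:
        raise DesignError(f"samples absent from sheet: {missing}")
    cols = pd.MultiIndex.from_arrays(
        [meta.loc[cm.columns, "time_h"], meta.loc[cm.columns, "replicate"]],
        names=["time_h", "replicate"],
    )
    out = cm.copy()
    out.columns = cols
    return out.sort_index(axis=1)


def build_expression_table(cm: pd.DataFrame, annotation: pd.DataFrame,
                           sheet: pd.DataFrame,
                           library_mode: str = "clean_reads") -> ExpressionTable:
    """Quantify a count matrix into per-replicate and merged RPKM.

    *library_mode* selects the per-sample library size: ``clean_reads``
    (mapped − rRNA from the sheet, the default) or the name of an explicit
    numeric column in the sheet.
    """
    meta = sheet.set_index("sample_id")
    if set(cm.columns) != set(meta.index):
        raise DesignError("count matrix samples and sample sheet disagree")
    times = sorted(meta["time_h"].unique())
    reps = sorted(meta["replicate"].unique())
    expected = {(t, r) for t in times for r in reps}
    got = set(zip(meta["time_h"], meta["replicate"]))
    if got != expected:
        raise DesignError(f"incomplete design: missing cells {sorted(expected - got)}")

    if library_mode == "clean_reads":
        lib = meta["mapped_reads"] - meta["rrna_reads"]
    elif library_mode in meta.columns:
        lib = pd.to_numeric(meta[library_mode])
    else:
        raise DesignError(f"unknown library_mode {library_mode!r}")
    if (lib <= 0).any():
        raise ValidationError("every sample needs a positive library size")

    lengths = annotation.set_index("gene_id")["length_bp"]
    missing = cm.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"genes without annotated length: {list(missing[:3])}")
    lengths = lengths.loc[cm.index].astype(float)

    counts = counts_by_condition(cm, sheet)
    lib_cond = pd.Series(
        lib.to_numpy(float),
        index=pd.MultiIndex.from_arrays(
            [meta["time_h"], meta["replicate"]], names=["time_h", "replicate"]),
    ).sort_index().loc[counts.columns]
    rep = pd.DataFrame(
        rpkm(counts.to_numpy(float),
             lengths.to_numpy()[:, None], lib_cond.to_numpy()[None, :]),
        index=counts.index, columns=counts.columns,
    )
    merged = rep.T.groupby(level="time_h").mean().T
    merged = merged[times]
    return ExpressionTable(counts=counts, rpkm_rep=rep, rpkm_merged=merged,
                           library_sizes=lib_cond, lengths_bp=lengths)


def sample_concordance_r2(et: ExpressionTable, time_h) -> float:
    """Squared Pearson correlation of the two replicate RPKM vectors at a time.

    The statistic the study used to judge replicate agreement (>0.98 at all
    times except the 24 h transition sample).
    """
    reps = et.replicates
    if len(reps) != 2:
        raise DesignError("replicate concordance is defined for 2 replicates")
    a = et.rpkm_rep[(time_h, reps[0])].to_numpy(float)
    b = et.rpkm_rep[(time_h, reps[1])].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise DesignError("need >= 3 genes with finite values in both replicates")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError(f"zero-variance replicate vector at {time_h} h")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
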