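"""Synthetic developmental time-course generator with ground truth.

Emulates the statistical design of the starvation time course the pipeline
targets: 7 time points (0, 6, 12, 24, 48, 72, 96 h), 2 biological
replicates, ~7229 annotated genes, a heavy rRNA load in the sequencing
summaries (~98% of mapped reads), and four latent gene classes —

* ``developmental``: genes following one of K temporal module shapes
  (log2 relative centroids mimicking the published module classes: two
  early-down shapes, three aggregation peaks, two transition peaks, two
  late/sporulation peaks and one V-shaped down-then-late-recovery shape),
* ``constitutive``: a shared low-amplitude trajectory whose total fold
  change stays below 2 — reproducible between replicates, as real
  filter-passing constitutive genes are, but not called developmental,
* ``low``: flat, tiny expected counts that trip the <50-read filter,
* ``discordant``: independent per-replicate log2 deviations, so the
  replicate trajectories disagree (r² below 0.7).

Expected counts are back-converted from the expected RPKM trajectories via
the RPKM formula at the configured library size; observed counts are drawn
negative-binomial (variance mu + dispersion·mu²) independently per
replicate.  Sample sheets are bookkeeping-consistent: clean reads equal the
count-matrix column totals exactly and mapped reads are inflated so the
rRNA rate matches the configured value (no rRNA gene rows are simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import validate_sample_sheet

#: K=10 log2 relative module shapes over (0, 6, 12, 24, 48, 72, 96) h,
#: listed in planted temporal order (ascending peak; ties resolved by the
#: final-time value exactly as the DG ordering rule resolves them).
DEFAULT_MODULE_SHAPES = np.array([
    [2.0, 0.3, -0.6, -1.0, -1.2, -1.3, -1.3],   # 1 down fast
    [1.6, 1.4, 0.6, -0.4, -1.0, -1.2, -1.0],    # 2 down slow
    [-0.5, 1.8, 0.8, -0.5, -1.0, -0.8, -0.6],   # 3 aggregation, 6 h peak
    [-1.0, 0.2, 1.8, 0.6, -0.6, -0.8, -0.8],    # 4 aggregation, 12 h peak
    [-1.2, -0.8, 0.3, 1.8, 0.5, -0.5, -0.8],    # 5 aggregation, 24 h peak
    [-1.2, -1.0, -0.5, 0.8, 1.7, 0.3, -0.4],    # 6 transition, 48 h peak
    [-1.4, -1.2, -0.8, 0.0, 1.6, 1.2, 0.6],     # 7 transition, sustained
    [-1.4, -1.2, -1.0, -0.5, 0.6, 1.8, 1.2],    # 8 sporulation, 72 h peak
    [0.8, -0.8, -1.2, -1.2, -0.8, 0.3, 1.4],    # 9 V-shaped late recovery
    [-1.2, -1.2, -1.1, -0.9, -0.4, 0.8, 2.0],   # 10 late sporulation
])


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic time course.

    Class fractions mirror the published composition: 19.6% developmental
    genes overall and 9.1% constitutive among the filter-passing set; the
    filtered remainder is split between low-count and replicate-discordant
    genes, with the low-count fraction dominating as in real bacterial
    total-RNA libraries.  ``frac_discordant=None`` means "whatever remains".
    """

    n_genes: int = 7229
    times_h: tuple = (0, 6, 12, 24, 48, 72, 96)
    n_reps: int = 2
    frac_developmental: float = 0.196
    frac_constitutive_of_passed: float = 0.091
    frac_low: float = 0.55
    frac_discordant: float | None = None
    n_modules: int = 10
    module_shapes: np.ndarray | None = None
    baseline_log_mean: float = float(np.log(80.0))   # ln RPKM
    baseline_log_sd: float = 1.2
    nb_dispersion: float = 0.005
    library_size: int = 1_000_000
    rrna_rate: float = 0.98
    gene_len_log_mean: float = 6.9   # ln bp, median ~1 kb
    gene_len_log_sd: float = 0.55
    constitutive_fold_range: tuple = (1.45, 1.9)
    discordant_log2_sd: float = 1.0
    low_count_range: tuple = (0.5, 30.0)
    min_expected_count: float = 250.0
    burst_log_sd: float = 0.0
    seed: int = 0

    def shapes(self) -> np.ndarray:
        s = DEFAULT_MODULE_SHAPES if self.module_shapes is None else np.asarray(
            self.module_shapes, float)
        if self.n_modules > len(s):
            raise ConfigurationError(
                f"n_modules={self.n_modules} exceeds the {len(s)} shape rows")
        if s.shape[1] != len(self.times_h):
            raise ConfigurationError("module shape width must match times_h")
        return s[: self.n_modules]

    def class_counts(self) -> dict[str, int]:
        n = self.n_genes
        f = self.frac_constitutive_of_passed
        n_dev = int(round(self.frac_developmental * n))
        n_con = int(round(n_dev * f / (1.0 - f)))
        n_low = int(round(self.frac_low * n))
        n_disc = (n - n_dev - n_con - n_low if self.frac_discordant is None
                  else int(round(self.frac_discordant * n)))
        counts = {"developmental": n_dev, "constitutive": n_con,
                  "low": n_low, "discordant": n_disc}
        if any(v < 0 for v in counts.values()) or sum(counts.values()) > n:
            raise ConfigurationError(f"infeasible class fractions: {counts}")
        counts["low"] += n - sum(counts.values())  # absorb rounding remainder
        return counts


@dataclass
class SimBundle:
    counts: pd.DataFrame       # genes × samples, int
    sheet: pd.DataFrame        # canonical sample sheet
    annotation: pd.DataFrame
    truth: pd.DataFrame        # gene_id, true_class, true_module, true_peak_time
    config: SimConfig = field(repr=False, default=None)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion·mu².

    dispersion = 0 is the deterministic limit (counts = rounded means).
    """
    if dispersion < 0:
        raise ConfigurationError("nb_dispersion must be >= 0")
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def _make_ids(n: int) -> list[str]:
    return [f"MXAN_RS{5 * (i + 1):05d}" for i in range(n)]


def _assemble(config: SimConfig, mu: np.ndarray, truth: pd.DataFrame,
              lengths: np.ndarray, rng: np.random.Generator) -> SimBundle:
    """Draw counts from expectations and build all bookkeeping tables."""
    g, t, r = mu.shape
    if config.burst_log_sd > 0:
        mu = mu * rng.lognormal(0.0, config.burst_log_sd, mu.shape)
    counts3 = _nb_draw(rng, mu, config.nb_dispersion)
    sample_ids = [f"WT_{config.times_h[i]}_{j + 1}" for i in range(t) for j in range(r)]
    counts = pd.DataFrame(counts3.reshape(g, t * r),
                          index=pd.Index(truth["gene_id"], name="gene_id"),
                          columns=sample_ids)
    clean = counts.sum(axis=0).to_numpy(np.int64)
    mapped = np.rint(clean / (1.0 - config.rrna_rate)).astype(np.int64)
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "time_h": [config.times_h[i] for i in range(t) for _ in range(r)],
        "replicate": [j + 1 for _ in range(t) for j in range(r)],
        "mapped_reads": mapped,
        "rrna_reads": mapped - clean,
    })
    validate_sample_sheet(sheet, origin="simulated sheet")
    annotation = pd.DataFrame({
        "gene_id": truth["gene_id"],
        "alt_id": [f"MXAN_{i + 1:04d}" for i in range(g)],
        "length_bp": lengths.astype(int),
        "name": "",
        "pathway": "",
    })
    return SimBundle(counts=counts, sheet=sheet, annotation=annotation,
                     truth=truth.reset_index(drop=True), config=config)


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate a full synthetic bundle with planted classes and modules."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n, t, r = config.n_genes, len(config.times_h), config.n_reps
    shapes = config.shapes()
    counts_by_class = config.class_counts()

    classes = np.concatenate([
        np.full(v, i) for i, v in enumerate(counts_by_class.values())
    ])
    rng.shuffle(classes)
    class_names = np.array(list(counts_by_class))[classes]

    lengths = np.clip(np.rint(rng.lognormal(
        config.gene_len_log_mean, config.gene_len_log_sd, n)), 150, 12000)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    count_per_rpkm = lengths * config.library_size / 1e9

    module = np.full(n, -1)
    dev = class_names == "developmental"
    module[dev] = rng.integers(0, config.n_modules, dev.sum())

    # expected RPKM trajectories, shared between replicates unless discordant
    traj = np.ones((n, t))
    traj[dev] = 2.0 ** shapes[module[dev]]
    con = class_names == "constitutive"
    if con.any():
        pick = rng.integers(0, config.n_modules, con.sum())
        folds = rng.uniform(*config.constitutive_fold_range, con.sum())
        s = shapes[pick]
        span = s.max(axis=1) - s.min(axis=1)
        traj[con] = 2.0 ** (s * (np.log2(folds) / span)[:, None])

    # detectability floor: reliable classes must clear the read filter
    reliable = dev | con | (class_names == "discordant")
    floor = (config.min_expected_count /
             (count_per_rpkm * traj.min(axis=1)))
    base = np.where(reliable, np.maximum(base, floor), base)

    low = class_names == "low"
    mu_rpkm = base[:, None, None] * traj[:, :, None] * np.ones((1, 1, r))
    if low.any():
        lo_counts = rng.uniform(*config.low_count_range, low.sum())
        mu_rpkm[low] = (lo_counts / count_per_rpkm[low])[:, None, None]
    disc = class_names == "discordant"
    if disc.any():
        dev_log2 = rng.normal(0.0, config.discordant_log2_sd, (disc.sum(), t, r))
        mu_rpkm[disc] = base[disc, None, None] * 2.0 ** dev_log2

    mu_counts = mu_rpkm * count_per_rpkm[:, None, None]

    peak_time = np.where(
        dev, np.asarray(config.times_h)[shapes.argmax(axis=1)][
            np.where(module >= 0, module, 0)], np.nan)
    truth = pd.DataFrame({
        "gene_id": _make_ids(n),
        "true_class": class_names,
        "true_module": pd.array(np.where(module >= 0, module + 1, -1),
                                dtype="Int64").to_numpy(),
        "true_peak_time": peak_time,
    })
    truth.loc[truth["true_module"] == -1, "true_module"] = pd.NA
    truth["true_module"] = pd.array(truth["true_module"], dtype="Int64")
    return _assemble(config, mu_counts, truth, lengths, rng)


def null_config(**overrides) -> SimConfig:
    """Exchangeable-null configuration for FDR calibration.

    Every gene gets one flat expectation shared by both replicates with
    strongly over-dispersed noise, making all 14 (time, replicate) cells of
    a gene i.i.d.: independent per-replicate time scrambles then leave the
    joint distribution — and hence the expected number of chance
    developmental calls — exactly unchanged, which is what makes the
    scrambling FDR estimator's ≈100% behaviour checkable.  The abundance
    and dispersion defaults put enough genes past the read filter and give
    the noise enough fold-change range that chance passes are plentiful
    (the ratio estimate is then stable across seeds).
    """
    cfg = SimConfig(nb_dispersion=0.01,
                    burst_log_sd=4.0,
                    baseline_log_mean=float(np.log(1e8)),
                    baseline_log_sd=0.5)
    return replace(cfg, **overrides)


def simulate_null(config: SimConfig | None = None) -> SimBundle:
    """Pure-null bundle: flat shared expectations, independent noisy replicates."""
    config = config or null_config()
    rng = np.random.default_rng(config.seed)
    n, t, r = config.n_genes, len(config.times_h), config.n_reps
    lengths = np.clip(np.rint(rng.lognormal(
        config.gene_len_log_mean, config.gene_len_log_sd, n)), 150, 12000)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    count_per_rpkm = lengths * config.library_size / 1e9
    mu_counts = (base * count_per_rpkm)[:, None, None] * np.ones((1, t, r))
    truth = pd.DataFrame({
        "gene_id": _make_ids(n),
        "true_class": "constitutive",
        "true_module": pd.array([pd.NA] * n, dtype="Int64"),
        "true_peak_time": np.nan,
    })
    return _assemble(config, mu_counts, truth, lengths, rng)


DEFAULT_CATEGORY_PROBS = {"up1": 0.10, "up2": 0.07, "down": 0.22,
                          "not_regulated": 0.61}


def simulate_categories(truth: pd.DataFrame, assoc_strength: float = 0.0,
                        target_dgs=frozenset({7, 8}), seed: int = 0,
                        base_probs: dict | None = None) -> pd.DataFrame:
    """External category labels with a planted module association.

    Labels the reliable genes (developmental + constitutive) with the
    external study's classes.  Genes whose true module is in *target_dgs*
    are relabelled ``up1``/``up2`` with probability *assoc_strength*;
    strength 0 gives label independence (the enrichment null), strength 1
    makes the targeted modules fully up-regulated externally.
    """
    if not 0 <= assoc_strength <= 1:
        raise ValidationError("assoc_strength must be in [0, 1]")
    if not len(truth):
        raise ValidationError("empty ground truth")
    probs = base_probs or DEFAULT_CATEGORY_PROBS
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    reliable = truth[truth["true_class"].isin(["developmental", "constitutive"])]
    cats = np.asarray(labels)[rng.choice(len(labels), len(reliable), p=p)]
    in_target = reliable["true_module"].isin(list(target_dgs)).to_numpy()
    flip = rng.random(len(reliable)) < assoc_strength
    ups = np.asarray(["up1", "up2"])[rng.integers(0, 2, len(reliable))]
    cats = np.where(in_target & flip, ups, cats)
    out = pd.DataFrame({"gene_id": reliable["gene_id"].to_numpy(),
                        "category": cats})
    out.attrs["labels"] = sorted(set(labels) | {"up1", "up2"})
    return out
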