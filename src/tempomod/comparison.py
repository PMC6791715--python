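"""Cross-dataset enrichment of temporal modules against external categories.

Given the DG membership from the starvation time course and an external
per-gene category table (e.g. the chemically induced sporulation
transcriptome's up1/up2/down/not-regulated classes), each (DG, category)
pair is tested on a 2×2 contingency table over the shared gene universe
{in DG / not in DG} × {in category / not in category} with a Pearson
chi-square (1 df, no continuity correction by default), flagged significant
at p < alpha (0.01) and directed by the sign of observed − expected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_half_up
from .errors import ValidationError


def shared_gene_universe(reliable_genes, categories: pd.DataFrame) -> list[str]:
    """Genes with a reliable call in both datasets (sorted intersection).

    *reliable_genes* is the time course's reliable set (DG-assigned plus
    constitutive); *categories* supplies the external study's gene list.
    """
    a, b = set(reliable_genes), set(categories["gene_id"])
    if not a or not b:
        raise ValidationError("both gene sets must be nonempty")
    shared = sorted(a & b)
    if not shared:
        raise ValidationError("empty intersection between the two datasets")
    return shared


def chi2_2x2(a: float, b: float, c: float, d: float, continuity: bool = False):
    """Pearson chi-square for a 2×2 table [[a, b], [c, d]], 1 df.

    Returns (chi2, p).  With *continuity*, the Yates-corrected statistic.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    den = r1 * r2 * c1 * c2
    if den == 0:
        return float("nan"), float("nan")
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff * diff / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def enrichment_test(dg_assignments: pd.DataFrame, categories: pd.DataFrame,
                    universe, alpha: float = 0.01, continuity: bool = False,
                    bh: bool = False) -> pd.DataFrame:
    """Per-(DG, category) chi-square enrichment over the shared universe.

    Returns one row per cell with observed, expected, chi2, p, direction
    (enriched/depleted), significant (p < alpha) and a ``reliable`` flag
    (expected >= 1; smaller expectations are reported but flagged, the
    chi-square approximation being poor there).  Cells whose expected count
    is exactly zero (an empty DG or category within the universe) are
    recorded with NaN statistics and a warning.  ``bh=True`` appends
    Benjamini–Hochberg adjusted p-values in ``p_bh``; the default
    significance rule stays the study's fixed p < alpha.
    """
    if len(universe) < 2:
        raise ValidationError("universe must contain at least 2 genes")
    uni = pd.Index(universe)
    n = len(uni)
    dg_of = dg_assignments["dg"].reindex(uni)
    cat_of = categories.set_index("gene_id")["category"].reindex(uni)
    rows = []
    for dg in sorted(dg_assignments["dg"].unique()):
        in_dg = (dg_of == dg).to_numpy()
        for cat in sorted(cat_of.dropna().unique()):
            in_cat = (cat_of == cat).to_numpy()
            a = int((in_dg & in_cat).sum())
            b = int((in_dg & ~in_cat).sum())
            c = int((~in_dg & in_cat).sum())
            d = n - a - b - c
            expected = (a + b) * (a + c) / n
            if expected == 0:
                warnings.warn(f"DG{dg} × {cat}: zero expected count, cell skipped",
                              stacklevel=2)
                rows.append(dict(dg=dg, category=cat, observed=a, expected=0.0,
                                 chi2=np.nan, p=np.nan, direction="depleted",
                                 significant=False, reliable=False, tested=False))
                continue
            chi2, p = chi2_2x2(a, b, c, d, continuity=continuity)
            rows.append(dict(dg=dg, category=cat, observed=a, expected=expected,
                             chi2=chi2, p=p,
                             direction="enriched" if a > expected else "depleted",
                             significant=bool(p < alpha), reliable=expected >= 1,
                             tested=True))
    out = pd.DataFrame(rows)
    if bh:
        from statsmodels.stats.multitest import multipletests

        mask = out["tested"].to_numpy()
        padj = np.full(len(out), np.nan)
        if mask.any():
            padj[mask] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_bh"] = padj
    return out


def permutation_significance_rate(dg_assignments: pd.DataFrame,
                                  categories: pd.DataFrame, universe,
                                  n_permutations: int = 1000,
                                  alpha: float = 0.01, seed: int = 0) -> float:
    """Fraction of (DG, category) cells significant under label permutation.

    Shuffles the category labels across the universe *n_permutations* times
    and pools the per-cell chi-square significance calls; on truly unrelated
    labels this calibration should return approximately *alpha*.
    """
    uni = pd.Index(universe)
    n = len(uni)
    dgs = dg_assignments["dg"].reindex(uni)
    dg_codes, dg_levels = pd.factorize(dgs.fillna(-1), sort=True)
    cats = categories.set_index("gene_id")["category"].reindex(uni)
    cat_codes, cat_levels = pd.factorize(cats, sort=True)
    # cells involving genes without a DG (constitutive) still count toward
    # the "not in DG" margin, exactly as in enrichment_test
    real_dg = [i for i, lev in enumerate(dg_levels) if lev != -1]
    rng = np.random.default_rng(seed)
    n_dg = len(dg_levels)
    n_cat = len(cat_levels)
    dg_tot = np.bincount(dg_codes, minlength=n_dg).astype(float)
    sig = 0
    total = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cat_codes)
        table = np.bincount(dg_codes * n_cat + perm,
                            minlength=n_dg * n_cat).reshape(n_dg, n_cat).astype(float)
        cat_tot = table.sum(axis=0)
        a = table[real_dg]
        r1 = dg_tot[real_dg][:, None]
        c1 = cat_tot[None, :]
        b = r1 - a
        c = c1 - a
        d = n - a - b - c
        den = r1 * (n - r1) * c1 * (n - c1)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = n * (a * d - b * c) ** 2 / den
            p = stats.chi2.sf(chi2, df=1)
        ok = den > 0
        sig += int((p[ok] < alpha).sum())
        total += int(ok.sum())
    return sig / total


def overlap_summary(dg_assignments: pd.DataFrame, categories: pd.DataFrame,
                    universe, down_dgs=(1,)) -> pd.DataFrame:
    """3×3 tally of external categories vs time-course regulation direction.

    Columns follow the study's convention: DG1 counts as the down-regulated
    developmental pool, DGs 2..K as up-regulated, and universe genes without
    a DG as constitutive.  External ``up*`` labels collapse to ``up``.
    Row percentages are given to one decimal; an empty row yields 0.0.
    """
    uni = pd.Index(universe)
    dg_of = dg_assignments["dg"].reindex(uni)
    cat_of = categories.set_index("gene_id")["category"].reindex(uni)

    def cat_group(label):
        if isinstance(label, str) and label.startswith("up"):
            return "up"
        if label == "down":
            return "down"
        return "not_regulated"

    def dev_group(dg):
        if pd.isna(dg):
            return "constitutive"
        return "down" if dg in down_dgs else "up"

    groups_cat = cat_of.map(cat_group)
    groups_dev = dg_of.map(dev_group)
    cols = ["up", "down", "constitutive"]
    rows = []
    for cg in ["up", "down", "not_regulated"]:
        counts = {c: int(((groups_cat == cg) & (groups_dev == c)).sum()) for c in cols}
        total = sum(counts.values())
        row = {"category": cg, **counts, "total": total}
        for c in cols:
            row[f"pct_{c}"] = round_half_up(100.0 * counts[c] / total, 1) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
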