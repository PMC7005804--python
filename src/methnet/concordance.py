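"""Pathway-score construction and concordance statistics.

Per pathway, the score is (number of genes in the pathway) x sig, where sig
discretizes the enrichment FDR p-value: 3 for p <= 1e-6, 2 for p in
(1e-6, 1e-5], 1 for p in (1e-5, 1e-4], and 0 when the pathway is not
enriched in that gene set.  Concordance between the two score vectors is
measured by Lin's concordance correlation coefficient (bootstrap CI),
Kendall's coefficient of concordance W (permutation p), OLS regression on
double-positive pairs, and a Bland-Altman analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "sig_value",
    "pathway_scores",
    "lin_ccc",
    "kendall_w",
    "bland_altman",
    "overlap_fraction",
    "score_regression",
    "concordance_report",
]

FDR_CONSIDER_THRESHOLD = 4e-4


def sig_value(fdr_p: float, enriched: bool, extended: bool = False) -> int:
    """Discretized statistical-signification level in {0, 1, 2, 3}.

    Interval endpoints are half-open on the left, closed on the right
    (p = 1e-5 -> sig 2).  With ``extended``, p in (1e-4, 4e-4) also maps to
    sig 1 so that every pathway under the 4e-4 consideration threshold
    receives a positive score.
    """
    if not enriched:
        return 0
    if not (0.0 <= fdr_p <= 1.0):
        raise ValueError(f"fdr_p outside [0, 1]: {fdr_p}")
    if fdr_p <= 1e-6:
        return 3
    if fdr_p <= 1e-5:
        return 2
    if fdr_p <= 1e-4:
        return 1
    if extended and fdr_p < FDR_CONSIDER_THRESHOLD:
        return 1
    return 0


def pathway_scores(enrich_dmg: pd.DataFrame, enrich_deg: pd.DataFrame,
                   fdr_threshold: float = FDR_CONSIDER_THRESHOLD,
                   extended: bool = False) -> pd.DataFrame:
    """Per-pathway score pairs from two enrichment tables.

    Each table needs columns pathway_id, n_genes_in_set, fdr_p.  The union of
    pathways passing ``fdr_threshold`` in at least one table is kept; where a
    pathway is absent (or above threshold) in one table its n_genes and sig
    are 0 there.
    """
    def _index(df: pd.DataFrame) -> pd.DataFrame:
        return df.set_index("pathway_id")[["n_genes_in_set", "fdr_p"]]

    dmg = _index(enrich_dmg)
    deg = _index(enrich_deg)
    keep = sorted(
        set(dmg.index[dmg["fdr_p"] < fdr_threshold])
        | set(deg.index[deg["fdr_p"] < fdr_threshold])
    )
    rows = []
    for pid in keep:
        rec: dict = {"pathway_id": pid}
        for key, table in (("dmg", dmg), ("deg", deg)):
            if pid in table.index and table.loc[pid, "fdr_p"] < fdr_threshold:
                n = int(table.loc[pid, "n_genes_in_set"])
                fdr = float(table.loc[pid, "fdr_p"])
                sig = sig_value(fdr, enriched=True, extended=extended)
            else:
                n, fdr, sig = 0, np.nan, 0
            rec[f"n_genes_{key}"] = n
            rec[f"fdr_{key}"] = fdr
            rec[f"sig_{key}"] = sig
            rec[f"p_{key}"] = n * sig
        rows.append(rec)
    return pd.DataFrame(rows, columns=[
        "pathway_id", "n_genes_dmg", "fdr_dmg", "sig_dmg", "p_dmg",
        "n_genes_deg", "fdr_deg", "sig_deg", "p_deg",
    ])


def lin_ccc(x, y, n_boot: int = 2000, seed: int = 0) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a nonparametric
    bootstrap percentile CI (2.5/97.5)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired vectors of length >= 3 required")

    def _ccc(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(), b.var()
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both vectors; CCC undefined")
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        return 2.0 * cov / (va + vb + (a.mean() - b.mean()) ** 2)

    point = _ccc(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        a, b = x[idx], y[idx]
        if a.var() == 0 and b.var() == 0:
            continue
        boots.append(_ccc(a, b))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def _kendall_w_stat(ranks: np.ndarray) -> float:
    """W with tie correction from an m x n matrix of within-rater ranks."""
    m, n = ranks.shape
    r_i = ranks.sum(axis=0)
    s = float(((r_i - r_i.mean()) ** 2).sum())
    t = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        t += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * t
    if denom <= 0:
        raise ValueError("all ratings tied; W undefined")
    return 12.0 * s / denom


def kendall_w(rating_matrix, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Kendall's coefficient of concordance for an m x n rating matrix
    (m raters, n items), tie-corrected, with a permutation p-value obtained
    by permuting each rater's ratings independently."""
    ratings = np.asarray(rating_matrix, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 3:
        raise ValueError("need an m x n matrix with m >= 2 raters, n >= 3 items")
    from scipy.stats import rankdata

    ranks = np.vstack([rankdata(row) for row in ratings])
    w_obs = _kendall_w_stat(ranks)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.vstack([rng.permutation(row) for row in ranks])
        if _kendall_w_stat(perm) >= w_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(w_obs), float(p)


def bland_altman(x, y) -> dict:
    """Bland-Altman agreement: per-item (mean, diff) plus mean_diff +/- 2*sd
    limits (sd with n-1 denominator) and the fraction of points within them."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired vectors of length >= 3 required")
    means = (x + y) / 2.0
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = mean_diff - 2.0 * sd, mean_diff + 2.0 * sd
    within = float(np.mean((diffs >= lo) & (diffs <= hi)))
    return {
        "means": means, "diffs": diffs, "mean_diff": mean_diff,
        "sd": sd, "lower_limit": lo, "upper_limit": hi,
        "fraction_within": within,
    }


def overlap_fraction(enriched_ids_a: set[str], enriched_ids_b: set[str]) -> float:
    """Jaccard overlap |A n B| / |A u B| of two enriched-pathway id sets."""
    a, b = set(enriched_ids_a), set(enriched_ids_b)
    if not a and not b:
        raise ValueError("both sets empty; overlap undefined")
    return len(a & b) / len(a | b)


def score_regression(p_dmg, p_deg) -> dict:
    """OLS of P_DEG on P_DMG restricted to pairs with both scores > 0."""
    x = np.asarray(p_dmg, dtype=float)
    y = np.asarray(p_deg, dtype=float)
    mask = (x > 0) & (y > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 double-positive score pairs")
    import statsmodels.api as sm

    res = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r_squared": float(res.rsquared),
        "slope_p": float(res.pvalues[1]),
        "n": int(mask.sum()),
    }


def concordance_report(scores: pd.DataFrame, n_boot: int = 2000,
                       n_perm: int = 999, seed: int = 0,
                       enriched_ids_a: set[str] | None = None,
                       enriched_ids_b: set[str] | None = None) -> dict:
    """Full concordance summary from a :func:`pathway_scores` table."""
    x = scores["p_dmg"].to_numpy(dtype=float)
    y = scores["p_deg"].to_numpy(dtype=float)
    ccc, lo, hi = lin_ccc(x, y, n_boot=n_boot, seed=seed)
    w, w_p = kendall_w(np.vstack([x, y]), n_perm=n_perm, seed=seed)
    ba = bland_altman(x, y)
    report = {
        "ccc": ccc, "ccc_ci": [lo, hi],
        "kendall_w": w, "kendall_w_p": w_p,
        "bland_altman": {
            "mean_diff": ba["mean_diff"], "sd": ba["sd"],
            "lower_limit": ba["lower_limit"], "upper_limit": ba["upper_limit"],
            "fraction_within": ba["fraction_within"],
        },
        "n_pathways": int(len(scores)),
    }
    try:
        report["regression"] = score_regression(x, y)
    except ValueError:
        report["regression"] = None
    if enriched_ids_a is not None and enriched_ids_b is not None:
        report["overlap_fraction"] = overlap_fraction(enriched_ids_a, enriched_ids_b)
    return report
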