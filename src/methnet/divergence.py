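"""Per-cytosine divergence statistics and signal-detection DMP classification.

Each control/treatment individual is compared site-by-site against the
pooled counts of a reference group.  Candidate sites pass a BH-adjusted
Fisher exact test; the final call applies a Hellinger-divergence cutoff
chosen on the ROC curve (Youden index) that separates control-individual
divergences (negatives, natural variability) from treatment-individual
divergences (positives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MethylomeSample

__all__ = [
    "SiteDivergence",
    "DMPSet",
    "pool_reference",
    "site_divergence",
    "divergence_table",
    "youden_cutoff",
    "call_dmps",
    "group_mean_level_difference",
]

JEFFREYS = (0.5, 0.5)


@dataclass(frozen=True)
class SiteDivergence:
    chrom: str
    pos: int
    strand: str
    sample_id: str
    p_sample: float
    p_ref: float
    tv: float
    tvb: float
    hd: float
    fisher_p: float


@dataclass
class DMPSet:
    """Classified DMPs with the Hellinger cutoff and alpha used."""

    cutoff: float
    youden_j: float
    alpha: float
    sites: pd.DataFrame  # chrom,pos,strand,sample_id,group,p_sample,p_ref,tv,tvb,hd,fisher_p,p_adj,direction

    def __len__(self) -> int:
        return len(self.sites)

    def for_individual(self, sample_id: str) -> pd.DataFrame:
        return self.sites[self.sites["sample_id"] == sample_id]


def pool_reference(reference_samples: list[MethylomeSample]) -> pd.DataFrame:
    """Sum methylated/total counts per site across reference individuals."""
    if not reference_samples:
        raise ValueError("empty reference set")
    frames = []
    for s in reference_samples:
        if s.group != "reference":
            raise ValueError(f"sample {s.sample_id} is not a reference sample")
        frames.append(s.sites[["chrom", "pos", "strand", "n_meth", "n_total"]])
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)[["n_meth", "n_total"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return pooled


@lru_cache(maxsize=200_000)
def _fisher_two_sided(k_s: int, n_s: int, k_r: int, n_r: int) -> float:
    table = [[k_s, n_s - k_s], [k_r, n_r - k_r]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _hd(p_s: np.ndarray, p_r: np.ndarray) -> np.ndarray:
    # squared Hellinger between Bernoulli(p_s) and Bernoulli(p_r)
    return (np.sqrt(p_s) - np.sqrt(p_r)) ** 2 + (np.sqrt(1 - p_s) - np.sqrt(1 - p_r)) ** 2


def divergence_table(sample: MethylomeSample, pooled_ref: pd.DataFrame,
                     prior: tuple[float, float] = JEFFREYS,
                     weighted: bool = True, fisher: bool = True) -> pd.DataFrame:
    """Vectorized per-site divergences of one individual vs the pooled reference.

    Sites absent from the pooled reference are dropped.  ``weighted`` applies
    the coverage weight 2*n_s*n_r/(n_s+n_r) to the squared-Hellinger term.
    ``fisher=False`` skips the exact test (fisher_p = NaN) when only the
    divergence columns are needed.
    """
    a, b = prior
    merged = sample.sites.merge(pooled_ref, on=["chrom", "pos", "strand"],
                                suffixes=("_s", "_r"), how="inner")
    n_s = merged["n_total_s"].to_numpy(dtype=float)
    n_r = merged["n_total_r"].to_numpy(dtype=float)
    k_s = merged["n_meth_s"].to_numpy(dtype=float)
    k_r = merged["n_meth_r"].to_numpy(dtype=float)
    if (n_s < 1).any() or (n_r < 1).any():
        raise ValueError("zero total counts")
    p_s = k_s / n_s
    p_r = k_r / n_r
    pt_s = (k_s + a) / (n_s + a + b)
    pt_r = (k_r + a) / (n_r + a + b)
    hd = _hd(p_s, p_r)
    if weighted:
        hd = hd * (2.0 * n_s * n_r / (n_s + n_r))
    if fisher:
        fisher_p = np.array([
            _fisher_two_sided(int(ks), int(ns), int(kr), int(nr))
            for ks, ns, kr, nr in zip(k_s, n_s, k_r, n_r)
        ])
    else:
        fisher_p = np.full(len(merged), np.nan)
    return pd.DataFrame({
        "chrom": merged["chrom"],
        "pos": merged["pos"],
        "strand": merged["strand"],
        "sample_id": sample.sample_id,
        "group": sample.group,
        "p_sample": p_s,
        "p_ref": p_r,
        "tv": p_s - p_r,
        "tvb": pt_s - pt_r,
        "hd": hd,
        "fisher_p": fisher_p,
    })


def site_divergence(sample_site_counts: tuple[int, int],
                    ref_site_counts: tuple[int, int],
                    prior: tuple[float, float] = JEFFREYS,
                    weighted: bool = True,
                    chrom: str = ".", pos: int = 0, strand: str = ".",
                    sample_id: str = ".") -> SiteDivergence:
    """Scalar divergence for a single site (counts given as (n_meth, n_total))."""
    k_s, n_s = sample_site_counts
    k_r, n_r = ref_site_counts
    if n_s < 1 or n_r < 1:
        raise ValueError("zero total counts")
    a, b = prior
    p_s, p_r = k_s / n_s, k_r / n_r
    hd = float(_hd(np.float64(p_s), np.float64(p_r)))
    if weighted:
        hd *= 2.0 * n_s * n_r / (n_s + n_r)
    return SiteDivergence(
        chrom=chrom, pos=pos, strand=strand, sample_id=sample_id,
        p_sample=p_s, p_ref=p_r, tv=p_s - p_r,
        tvb=(k_s + a) / (n_s + a + b) - (k_r + a) / (n_r + a + b),
        hd=hd, fisher_p=_fisher_two_sided(k_s, n_s, k_r, n_r),
    )


def youden_cutoff(negative_scores, positive_scores) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1 over observed thresholds.

    A score counts as positive when score >= cutoff.  Ties in J are broken by
    the smallest qualifying cutoff.
    """
    neg = np.asarray(negative_scores, dtype=float)
    pos = np.asarray(positive_scores, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([neg, pos]))
    if thresholds.size == 1:
        warnings.warn("all scores identical; J = 0", stacklevel=2)
        return float(thresholds[0]), 0.0
    # sensitivity(t) = P(pos >= t), specificity(t) = P(neg < t)
    sens = 1.0 - np.searchsorted(np.sort(pos), thresholds, side="left") / pos.size
    spec = np.searchsorted(np.sort(neg), thresholds, side="left") / neg.size
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[0]  # smallest threshold among ties
    return float(thresholds[best]), float(j[best])


def call_dmps(samples: list[MethylomeSample], reference: list[MethylomeSample],
              alpha: float = 0.05, adjust: str = "fdr_bh",
              weighted: bool = True,
              prior: tuple[float, float] = JEFFREYS) -> DMPSet:
    """Classify DMPs for every control and treatment individual.

    Steps: per-individual divergences vs the pooled reference; BH-adjusted
    Fisher p <= alpha defines candidates; the Hellinger cutoff is the Youden
    maximizer with control candidates as negatives and treatment candidates
    as positives; DMPs are candidates with hd >= cutoff, kept per individual
    with direction = sign(tv).
    """
    groups = {s.group for s in samples}
    if "control" not in groups or "treatment" not in groups:
        raise ValueError("samples must include at least one control and one treatment individual")
    pooled = pool_reference(reference)
    div = pd.concat(
        [divergence_table(s, pooled, prior=prior, weighted=weighted) for s in samples],
        ignore_index=True,
    )
    p_adj = multipletests(div["fisher_p"].to_numpy(), method=adjust)[1]
    div = div.assign(p_adj=p_adj)
    cand = div[div["p_adj"] <= alpha]
    neg = cand.loc[cand["group"] == "control", "hd"].to_numpy()
    pos = cand.loc[cand["group"] == "treatment", "hd"].to_numpy()
    if len(cand) == 0 or neg.size == 0 or pos.size == 0:
        warnings.warn("no candidate sites survive the Fisher/BH filter", stacklevel=2)
        return DMPSet(cutoff=float("nan"), youden_j=float("nan"), alpha=alpha,
                      sites=div.iloc[0:0].assign(direction=pd.Series(dtype=str)))
    cutoff, j = youden_cutoff(neg, pos)
    dmps = cand[cand["hd"] >= cutoff].copy()
    dmps["direction"] = np.where(dmps["tv"] >= 0, "hyper", "hypo")
    dmps = dmps.sort_values(["chrom", "pos", "sample_id"], kind="mergesort").reset_index(drop=True)
    return DMPSet(cutoff=cutoff, youden_j=j, alpha=alpha, sites=dmps)


def group_mean_level_difference(samples: list[MethylomeSample],
                                reference: list[MethylomeSample],
                                group: str) -> dict[tuple[str, int], float]:
    """Per-site group mean of (p_sample - p_ref) for WIG export."""
    pooled = pool_reference(reference)
    frames = [divergence_table(s, pooled) for s in samples if s.group == group]
    if not frames:
        raise ValueError(f"no samples in group {group!r}")
    div = pd.concat(frames, ignore_index=True)
    means = div.groupby(["chrom", "pos"])["tv"].mean()
    return {(chrom, int(pos)): float(v) for (chrom, pos), v in means.items()}
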