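"""Window-based DMR calling between a wild-type and a mutant methylome.

The caller follows a scan → merge → filter → test scheme per context:

1. tile each chromosome with non-overlapping 50-nt windows and flag windows
   where both genotypes have at least one covered cytosine of the context
   and the pooled level difference reaches the context threshold
   (CHH 10%, CHG 20%, CG 40%);
2. merge flagged windows separated by at most 100 nt — windows further
   apart are independent regions;
3. recompute pooled counts over the merged region and keep it only if it is
   at least 100 nt long, contains at least 20 cytosine sites, still meets
   the context difference threshold, and a two-sided Fisher's exact test on
   the pooled 2x2 count table gives p < 0.001.

Replicates are pooled by count summation before calling.  Fisher's test is
computed by exact integer hypergeometric enumeration (no asymptotics), so
p-values are reproducible to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CONTEXTS, GenomicInterval, MethylomeSample

logger = logging.getLogger(__name__)

#: per-context minimum absolute methylation difference
DEFAULT_MIN_DIFF = {"CHH": 0.10, "CHG": 0.20, "CG": 0.40}

HYPO = "hypo"
HYPER = "hyper"


@dataclass(frozen=True)
class DmrParams:
    """Window, merge, filter and test parameters for DMR calling."""

    window: int = 50
    max_gap: int = 100
    min_length: int = 100
    min_sites: int = 20
    min_diff: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_DIFF))
    alpha: float = 0.001
    #: count cytosine positions covered in BOTH genotypes ("covered_both")
    #: or every annotated cytosine position ("annotated")
    site_count_mode: str = "covered_both"

    def __post_init__(self) -> None:
        if min(self.window, self.max_gap, self.min_length,
               self.min_sites) <= 0 or self.alpha <= 0:
            raise ValueError("all DmrParams must be positive")
        if set(self.min_diff) != set(CONTEXTS):
            raise ValueError("min_diff must be keyed by CG, CHG and CHH")
        if self.site_count_mode not in ("covered_both", "annotated"):
            raise ValueError(f"bad site_count_mode {self.site_count_mode!r}")


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated region.

    Direction is the mutant relative to wild-type: hypo when the mutant
    level is lower.  ``counts`` stores the pooled 2x2 Fisher table
    (wt_meth, wt_unmeth, mut_meth, mut_unmeth), so every filter can be
    re-checked from the object itself.
    """

    location: GenomicInterval
    context: str
    direction: str
    wt_level: float
    mut_level: float
    n_sites: int
    p_value: float
    counts: Tuple[int, int, int, int]

    def passes_filters(self, params: DmrParams) -> bool:
        return (self.location.length() >= params.min_length
                and self.n_sites >= params.min_sites
                and abs(self.mut_level - self.wt_level)
                >= params.min_diff[self.context] - 1e-12
                and self.p_value < params.alpha)


def pool_replicates(samples: Sequence[MethylomeSample]) -> MethylomeSample:
    """Sum counts across replicates of one genotype, per (chrom,pos,strand).

    A site present in only some replicates keeps the counts it has; the
    context must agree wherever a site is shared.
    """
    if not samples:
        raise ValueError("no samples to pool")
    genotypes = {s.genotype for s in samples}
    if len(genotypes) != 1:
        raise ValueError(f"cannot pool across genotypes {sorted(genotypes)}")
    genome: Dict[str, int] = {}
    for s in samples:
        for chrom, ln in s.genome.items():
            genome[chrom] = max(genome.get(chrom, 0), ln)
    merged = pd.concat([s.sites for s in samples], ignore_index=True)
    grouped = merged.groupby(["chrom", "pos", "strand"], as_index=False).agg(
        count_meth=("count_meth", "sum"),
        count_unmeth=("count_unmeth", "sum"),
        context=("context", "first"),
        n_contexts=("context", "nunique"),
        trinucleotide=("trinucleotide", "first"))
    if (grouped["n_contexts"] > 1).any():
        bad = grouped[grouped["n_contexts"] > 1].iloc[0]
        raise ValueError(
            f"context disagreement between replicates at "
            f"{bad.chrom}:{bad.pos}({bad.strand})")
    grouped = grouped.drop(columns="n_contexts")
    grouped = grouped[["chrom", "pos", "strand", "count_meth",
                       "count_unmeth", "context", "trinucleotide"]]
    return MethylomeSample(genotype=samples[0].genotype,
                           replicate="pooled", sites=grouped, genome=genome)


#: above this grand total, enumeration switches from exact integers to
#: vectorized log-space hypergeometric probabilities
_EXACT_ENUMERATION_LIMIT = 2000


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on the table ((a, b), (c, d)).

    With margins fixed, sums the hypergeometric probabilities of every
    table at most as probable as the observed one.  Small tables use exact
    integer arithmetic; large ones a vectorized log-pmf sum with the
    customary 1e-7 relative tie tolerance.  A zero row or column margin
    gives p = 1.0 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    k = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(k, r1)
    if n <= _EXACT_ENUMERATION_LIMIT:
        # numerators share the denominator C(n, k); compare as integers
        num_obs = comb(r1, a) * comb(r2, c)
        total = 0
        for x in range(lo, hi + 1):
            nx = comb(r1, x) * comb(r2, k - x)
            if nx <= num_obs:
                total += nx
        return min(1.0, total / comb(n, k))
    from scipy.stats import hypergeom

    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, r1, k)
    log_obs = hypergeom.logpmf(a, n, r1, k)
    keep = logpmf <= log_obs + np.log1p(1e-7)
    return float(min(1.0, np.exp(logpmf[keep]).sum()))


def _window_counts(sample: MethylomeSample, context: str,
                   window: int) -> pd.DataFrame:
    """Per-window pooled counts for one sample and context."""
    sites = sample.subset_context(context)
    pos0 = sites["pos"].to_numpy(dtype=np.int64) - 1
    m = sites["count_meth"].to_numpy(dtype=np.int64)
    u = sites["count_unmeth"].to_numpy(dtype=np.int64)
    covered = (m + u) > 0
    df = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "start": (pos0 // window) * window,
        "meth": m, "cov": m + u,
        "n_covered": covered.astype(np.int64),
        "n_sites": np.ones(len(sites), dtype=np.int64)})
    return df.groupby(["chrom", "start"], as_index=False).sum()


def scan_windows(wt: MethylomeSample, mut: MethylomeSample, context: str,
                 params: Optional[DmrParams] = None) -> pd.DataFrame:
    """Candidate 50-nt windows for one context.

    A tiling window is a candidate iff both genotypes have >= 1 covered
    site of the context in it and the absolute pooled level difference
    meets the context threshold.  Returns a sorted DataFrame with per-window
    counts and levels for both genotypes.
    """
    params = params or DmrParams()
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    w = _window_counts(wt, context, params.window)
    m = _window_counts(mut, context, params.window)
    joined = w.merge(m, on=["chrom", "start"], how="inner",
                     suffixes=("_wt", "_mut"))
    joined = joined[(joined["n_covered_wt"] > 0)
                    & (joined["n_covered_mut"] > 0)].copy()
    joined["wt_level"] = joined["meth_wt"] / joined["cov_wt"]
    joined["mut_level"] = joined["meth_mut"] / joined["cov_mut"]
    diff = joined["mut_level"] - joined["wt_level"]
    threshold = params.min_diff[context]
    candidates = joined[np.abs(diff) >= threshold - 1e-12].copy()
    candidates["end"] = candidates["start"] + params.window
    candidates = candidates.sort_values(["chrom", "start"],
                                        ignore_index=True)
    cols = ["chrom", "start", "end", "meth_wt", "cov_wt", "meth_mut",
            "cov_mut", "wt_level", "mut_level"]
    return candidates[cols]


def merge_candidates(windows: pd.DataFrame,
                     max_gap: int = 100) -> List[GenomicInterval]:
    """Merge candidate windows whose gap is <= ``max_gap`` nt.

    The gap is measured from the end of one window to the start of the
    next (end-exclusive coordinates); windows further apart than
    ``max_gap`` start independent regions.
    """
    regions: List[GenomicInterval] = []
    for chrom, g in windows.groupby("chrom", sort=True):
        g = g.sort_values("start")
        cur_start = cur_end = None
        for start, end in zip(g["start"], g["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start - cur_end <= max_gap:
                cur_end = max(cur_end, end)
            else:
                regions.append(GenomicInterval(str(chrom), int(cur_start),
                                               int(cur_end)))
                cur_start, cur_end = start, end
        if cur_start is not None:
            regions.append(GenomicInterval(str(chrom), int(cur_start),
                                           int(cur_end)))
    return regions


def _region_table(wt_sites: pd.DataFrame, mut_sites: pd.DataFrame,
                  region: GenomicInterval, site_count_mode: str):
    """Pooled 2x2 counts and the qualifying site count within a region."""
    def in_region(df: pd.DataFrame) -> pd.DataFrame:
        pos0 = df["pos"] - 1
        return df[(df["chrom"] == region.chrom) & (pos0 >= region.start)
                  & (pos0 < region.end)]

    w = in_region(wt_sites)
    m = in_region(mut_sites)
    wt_meth = int(w["count_meth"].sum())
    wt_cov = wt_meth + int(w["count_unmeth"].sum())
    mut_meth = int(m["count_meth"].sum())
    mut_cov = mut_meth + int(m["count_unmeth"].sum())

    w_cov = w[(w["count_meth"] + w["count_unmeth"]) > 0]
    m_cov = m[(m["count_meth"] + m["count_unmeth"]) > 0]
    if site_count_mode == "covered_both":
        shared = pd.merge(w_cov[["pos", "strand"]], m_cov[["pos", "strand"]],
                          on=["pos", "strand"], how="inner")
        n_sites = len(shared)
    else:  # annotated: every cytosine position present in either table
        union = pd.concat([w[["pos", "strand"]], m[["pos", "strand"]]]
                          ).drop_duplicates()
        n_sites = len(union)
    return (wt_meth, wt_cov, mut_meth, mut_cov, n_sites)


def call_dmrs(wt: MethylomeSample, mut: MethylomeSample, context: str,
              params: Optional[DmrParams] = None) -> List[Dmr]:
    """Full DMR calling for one context between pooled wt and mutant.

    scan → merge → per-region recomputation over *all* covered context
    sites in the region → length/site/difference/Fisher filters.  Output is
    sorted by (chrom, start).
    """
    params = params or DmrParams()
    if wt.n_sites() == 0 or mut.n_sites() == 0:
        logger.warning("empty input sample; no DMRs called")
        return []
    windows = scan_windows(wt, mut, context, params)
    regions = merge_candidates(windows, params.max_gap)
    wt_sites = wt.subset_context(context)
    mut_sites = mut.subset_context(context)
    threshold = params.min_diff[context]
    dmrs: List[Dmr] = []
    for region in regions:
        if region.length() < params.min_length:
            continue
        wt_meth, wt_cov, mut_meth, mut_cov, n_sites = _region_table(
            wt_sites, mut_sites, region, params.site_count_mode)
        if n_sites < params.min_sites or wt_cov == 0 or mut_cov == 0:
            continue
        wt_level = wt_meth / wt_cov
        mut_level = mut_meth / mut_cov
        diff = mut_level - wt_level
        if abs(diff) < threshold - 1e-12:
            continue
        p = fisher_exact_2x2(wt_meth, wt_cov - wt_meth,
                             mut_meth, mut_cov - mut_meth)
        if not p < params.alpha:
            continue
        dmrs.append(Dmr(
            location=region, context=context,
            direction=HYPO if diff < 0 else HYPER,
            wt_level=wt_level, mut_level=mut_level, n_sites=n_sites,
            p_value=p,
            counts=(wt_meth, wt_cov - wt_meth, mut_meth,
                    mut_cov - mut_meth)))
    dmrs.sort(key=lambda d: (d.location.chrom, d.location.start))
    return dmrs


def call_dmrs_all_contexts(wt: MethylomeSample, mut: MethylomeSample,
                           params: Optional[DmrParams] = None
                           ) -> Dict[str, List[Dmr]]:
    """Convenience: call DMRs independently for CG, CHG and CHH."""
    return {ctx: call_dmrs(wt, mut, ctx, params) for ctx in CONTEXTS}
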