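"""Site-, bin- and genome-level methylation frequencies.

Every aggregation tier uses the *weighted* (count-pooled) methylation level:
total methylated reads over total reads across the cytosines considered —
never the unweighted mean of per-site frequencies.  Missing levels (zero
covered reads) are represented as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .io import CONTEXTS, CytosineSite, MethylomeSample


def site_frequency(site: Union[CytosineSite, Tuple[int, int]]) -> float:
    """Per-site methylation frequency: meth / (meth + unmeth).

    NaN when the site has zero coverage.  Accepts a CytosineSite or a
    bare (count_meth, count_unmeth) pair.
    """
    if isinstance(site, CytosineSite):
        m, u = site.count_meth, site.count_unmeth
    else:
        m, u = site
    cov = m + u
    if cov == 0:
        return float("nan")
    return m / cov


def site_frequencies(sites: pd.DataFrame) -> np.ndarray:
    """Vectorized per-site frequencies (NaN at zero coverage)."""
    m = sites["count_meth"].to_numpy(dtype=float)
    cov = m + sites["count_unmeth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cov > 0, m / cov, np.nan)


@dataclass
class BinnedLevels:
    """Pooled methylation level per non-overlapping genomic bin.

    ``table`` columns: chrom, bin_start (0-based), total_meth, total_c,
    level (NaN when total_c == 0).  Bins with no annotated cytosine of the
    requested context are omitted entirely.
    """

    bin_size: int
    context: str
    table: pd.DataFrame


def bin_levels(sample: MethylomeSample, bin_size: int = 50,
               context: str = "all") -> BinnedLevels:
    """Pooled level per tiling ``bin_size``-nt bin.

    Per bin: sum of methylated counts over sum of coverages across all
    sites of the requested context, per the 50-nt bin convention.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    sites = sample.subset_context(context)
    pos0 = sites["pos"].to_numpy(dtype=np.int64) - 1
    bin_start = (pos0 // bin_size) * bin_size
    grouped = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy(),
        "bin_start": bin_start,
        "total_meth": sites["count_meth"].to_numpy(dtype=np.int64),
        "total_c": (sites["count_meth"] + sites["count_unmeth"]).to_numpy(
            dtype=np.int64),
    }).groupby(["chrom", "bin_start"], as_index=False).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(grouped["total_c"] > 0,
                         grouped["total_meth"] / grouped["total_c"], np.nan)
    grouped["level"] = level
    return BinnedLevels(bin_size=bin_size, context=context, table=grouped)


@dataclass
class GlobalLevels:
    """Genome-wide weighted methylation level per context.

    ``totals`` maps context → (total_meth, total_c); ``level`` returns the
    pooled fraction, NaN when the context has no covered site.
    """

    sample: str
    totals: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def level(self, context: str) -> float:
        m, c = self.totals.get(context, (0, 0))
        if c == 0:
            return float("nan")
        return m / c

    def percentage(self, context: str, decimals: int = 2) -> str:
        """Level as a percentage string, e.g. 0.2237 → ``"22.37%"``."""
        lv = self.level(context)
        if np.isnan(lv):
            return "NA"
        return f"{100.0 * lv:.{decimals}f}%"


def global_levels(sample: MethylomeSample) -> GlobalLevels:
    """Per-context pooled methylation over the whole genome."""
    totals: Dict[str, Tuple[int, int]] = {}
    for context, g in sample.sites.groupby("context", sort=True):
        m = int(g["count_meth"].sum())
        c = m + int(g["count_unmeth"].sum())
        totals[str(context)] = (m, c)
    return GlobalLevels(sample=sample.label, totals=totals)


def relative_reduction(reference: GlobalLevels, test: GlobalLevels,
                       context: str) -> float:
    """Percent loss of methylation relative to the reference:
    100 * (reference - test) / reference."""
    ref = reference.level(context)
    if not ref > 0:
        raise ValueError(
            f"reference level for {context} is zero or missing")
    return 100.0 * (ref - test.level(context)) / ref


def levels_table(levels: GlobalLevels, decimals: int = 2) -> pd.DataFrame:
    """Tidy per-context summary (counts, fraction, formatted percentage)."""
    rows = []
    for context in CONTEXTS:
        m, c = levels.totals.get(context, (0, 0))
        rows.append({
            "context": context, "total_meth": m, "total_c": c,
            "level": levels.level(context),
            "percent": levels.percentage(context, decimals)})
    return pd.DataFrame(rows)
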