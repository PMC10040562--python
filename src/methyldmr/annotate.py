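"""Assignment of DMRs to genomic features and cross-genotype overlaps.

A DMR maps to a promoter (200 bp upstream of the first exon), a gene body
(first through last exon) or a TE when at least 50% of the DMR's length
overlaps that single feature.  Promoter takes precedence over gene body
when both reach 50%; a DMR matching both a gene element and a TE falls in
the combined category.  Summary tables report promoter/body/TE columns the
way DMR-mapping tables are conventionally printed: the combined category is
tallied in its own column *and* inside the gene-element and TE columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dmr import Dmr, HYPER, HYPO
from .io import FeatureSet, GenomicInterval

PROMOTER = "promoter"
GENE_BODY = "gene_body"
TE = "te"
GENE_ELEMENT_AND_TE = "gene_element_and_te"
OTHER = "other"

CATEGORIES = (PROMOTER, GENE_BODY, TE, GENE_ELEMENT_AND_TE, OTHER)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals`` (the tables' printing precision)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def format_fraction(numerator: int, denominator: int,
                    decimals: int = 2) -> str:
    """Narrative-style fraction, e.g. (485, 814) → ``"59.58% (485/814)"``."""
    if denominator == 0:
        return "NA"
    return (f"{100.0 * numerator / denominator:.{decimals}f}% "
            f"({numerator}/{denominator})")


@dataclass
class DmrAssignment:
    """One DMR's feature matches and derived category.

    ``gene_element`` records which gene element (promoter or gene_body)
    matched, independent of whether a TE also matched, so overlapping table
    columns can be tallied without re-querying.
    """

    dmr: Dmr
    category: str
    gene_ids: Tuple[str, ...] = ()
    te_ids: Tuple[str, ...] = ()
    gene_element: Optional[str] = None  # PROMOTER or GENE_BODY or None

    @property
    def direction(self) -> str:
        return self.dmr.direction


def _max_overlap(dmr_iv: GenomicInterval,
                 intervals: Iterable[GenomicInterval]) -> int:
    return max((dmr_iv.overlap(iv) for iv in intervals), default=0)


def assign_dmr(dmr: Dmr, features: FeatureSet,
               min_fraction: float = 0.5) -> DmrAssignment:
    """Categorize one DMR against promoters, gene bodies and TEs.

    A match requires >= ``min_fraction`` of the DMR's length to overlap a
    single feature.  All genes/TEs reaching the threshold are recorded;
    promoter precedence applies when both promoter and body reach it.
    """
    iv = dmr.location
    needed = min_fraction * iv.length()

    prom_hits = [g for g, p in features.query_promoters(iv.chrom, iv.start,
                                                        iv.end)
                 if iv.overlap(p) >= needed]
    body_hits = [g for g in features.query_genes(iv.chrom, iv.start, iv.end)
                 if iv.overlap(g.body) >= needed]
    te_hits = [t for t in features.query_tes(iv.chrom, iv.start, iv.end)
               if iv.overlap(t.location) >= needed]

    gene_element = None
    gene_ids: Tuple[str, ...] = ()
    if prom_hits:
        gene_element = PROMOTER
        gene_ids = tuple(sorted(g.id for g in prom_hits))
    elif body_hits:
        gene_element = GENE_BODY
        gene_ids = tuple(sorted(g.id for g in body_hits))
    te_ids = tuple(sorted(t.id for t in te_hits))

    if gene_element and te_ids:
        category = GENE_ELEMENT_AND_TE
    elif te_ids:
        category = TE
    elif gene_element:
        category = gene_element
    else:
        category = OTHER
    return DmrAssignment(dmr=dmr, category=category, gene_ids=gene_ids,
                         te_ids=te_ids, gene_element=gene_element)


def assign_dmrs(dmrs: Sequence[Dmr], features: FeatureSet,
                min_fraction: float = 0.5) -> List[DmrAssignment]:
    return [assign_dmr(d, features, min_fraction) for d in dmrs]


def _tally(assignments: Sequence[DmrAssignment]) -> Dict[str, int]:
    total = len(assignments)
    prom = sum(1 for a in assignments if a.gene_element == PROMOTER)
    body = sum(1 for a in assignments if a.gene_element == GENE_BODY)
    te = sum(1 for a in assignments if a.te_ids)
    both = sum(1 for a in assignments if a.category == GENE_ELEMENT_AND_TE)
    other = sum(1 for a in assignments if a.category == OTHER)
    return {"total": total, "gene_elements": prom + body, "promoter": prom,
            "gene_body": body, "te": te, "gene_element_and_te": both,
            "other": other}


def tabulate_categories(assignments: Sequence[DmrAssignment],
                        direction_split: bool = True,
                        decimals: int = 1) -> pd.DataFrame:
    """DMR-by-genomic-region summary table for one genotype/context.

    Rows: hypermethylated / hypomethylated (when ``direction_split``) and
    total.  The gene-element column is promoter + gene body; DMRs matching
    both a gene element and a TE are counted in their own column and also
    inside the gene-element and TE columns, so the overlapping percentages
    reproduce the conventional table arithmetic.
    """
    rows = []
    groups: List[Tuple[str, Sequence[DmrAssignment]]] = []
    if direction_split:
        groups.append(("hypermethylated",
                       [a for a in assignments if a.direction == HYPER]))
        groups.append(("hypomethylated",
                       [a for a in assignments if a.direction == HYPO]))
    groups.append(("total", list(assignments)))
    for label, group in groups:
        tally = _tally(group)
        row: Dict[str, object] = {"type": label, "total": tally["total"]}
        for col in ("gene_elements", "promoter", "gene_body", "te",
                    "gene_element_and_te", "other"):
            row[col] = tally[col]
            row[f"{col}_pct"] = percent(tally[col], tally["total"], decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def superfamily_summary(assignments: Sequence[DmrAssignment],
                        features: FeatureSet, direction: str = "all",
                        min_proportion: float = 0.0) -> pd.DataFrame:
    """Distinct TEs targeted by DMRs, per TE superfamily.

    ``direction`` restricts to hypo- or hypermethylated DMRs.
    Superfamilies whose proportion of targeted TEs falls below
    ``min_proportion`` are folded into an "Others" row.
    """
    te_lookup = features.te_by_id()
    targeted: Set[str] = set()
    for a in assignments:
        if direction != "all" and a.direction != direction:
            continue
        targeted.update(a.te_ids)
    counts: Dict[str, int] = {}
    for te_id in targeted:
        te = te_lookup.get(te_id)
        if te is None:
            raise KeyError(f"TE {te_id!r} not present in the FeatureSet")
        counts[te.superfamily] = counts.get(te.superfamily, 0) + 1
    total = sum(counts.values())
    rows = []
    folded = 0
    for sf in sorted(counts, key=lambda s: (-counts[s], s)):
        prop = counts[sf] / total if total else float("nan")
        if min_proportion > 0 and prop < min_proportion:
            folded += counts[sf]
        else:
            rows.append({"superfamily": sf, "n_tes": counts[sf],
                         "proportion": prop})
    if folded:
        rows.append({"superfamily": "Others", "n_tes": folded,
                     "proportion": folded / total})
    return pd.DataFrame(rows,
                        columns=["superfamily", "n_tes", "proportion"])


def family_representation(assignments: Sequence[DmrAssignment],
                          features: FeatureSet, direction: str = HYPER,
                          min_fraction: float = 0.10) -> pd.DataFrame:
    """TE families with more than ``min_fraction`` of members targeted.

    A family qualifies when (distinct targeted members)/(family size)
    strictly exceeds the threshold; empty families are excluded.
    """
    sizes = features.family_sizes()
    te_lookup = features.te_by_id()
    targeted_by_family: Dict[str, Set[str]] = {}
    for a in assignments:
        if direction != "all" and a.direction != direction:
            continue
        for te_id in a.te_ids:
            te = te_lookup.get(te_id)
            if te is None:
                raise KeyError(f"TE {te_id!r} not present in the FeatureSet")
            targeted_by_family.setdefault(te.family, set()).add(te_id)
    rows = []
    for family in sorted(targeted_by_family):
        size = sizes.get(family, 0)
        if size == 0:
            continue
        n = len(targeted_by_family[family])
        fraction = n / size
        if fraction > min_fraction:
            rows.append({"family": family,
                         "superfamily": features.family_to_superfamily[
                             family],
                         "n_targeted": n, "family_size": size,
                         "fraction": fraction})
    return pd.DataFrame(rows, columns=["family", "superfamily", "n_targeted",
                                       "family_size", "fraction"])


@dataclass
class OverlapSummary:
    """Venn-style decomposition of per-genotype targeted-feature sets.

    ``cells`` maps each non-empty genotype subset (frozenset of labels) to
    the number of features targeted in exactly those genotypes; the cells
    are disjoint and together cover the union.
    """

    labels: Tuple[str, ...]
    sets: Dict[str, Set[str]]
    cells: Dict[frozenset, int]

    def total(self, label: str) -> int:
        return len(self.sets[label])

    def unique(self, label: str) -> int:
        return self.cells.get(frozenset([label]), 0)

    def unique_fraction(self, label: str, decimals: int = 2) -> str:
        """Formatted unique fraction, e.g. ``"59.58% (485/814)"``."""
        return format_fraction(self.unique(label), self.total(label),
                               decimals)

    def shared(self, *labels: str) -> int:
        """Features present in all the given genotypes (intersection)."""
        inter = set.intersection(*(self.sets[l] for l in labels))
        return len(inter)

    def pairwise_shared_fraction(self, a: str, b: str,
                                 decimals: int = 1) -> str:
        """Shared count over the union of the pair, formatted."""
        union = len(self.sets[a] | self.sets[b])
        return format_fraction(self.shared(a, b), union, decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"members": "+".join(sorted(k)), "count": v}
                for k, v in sorted(self.cells.items(),
                                   key=lambda kv: (len(kv[0]),
                                                   sorted(kv[0])))]
        return pd.DataFrame(rows, columns=["members", "count"])


def overlap_summary(per_genotype_sets: Mapping[str, Iterable[str]]
                    ) -> OverlapSummary:
    """Decompose >=2 genotype feature-id sets into disjoint Venn cells."""
    labels = tuple(per_genotype_sets)
    if len(labels) < 2:
        raise ValueError("need at least two genotypes")
    sets = {k: set(v) for k, v in per_genotype_sets.items()}
    membership: Dict[str, frozenset] = {}
    for label in labels:
        for item in sets[label]:
            membership[item] = membership.get(item, frozenset()) | {label}
    cells: Dict[frozenset, int] = {}
    for item, members in membership.items():
        cells[members] = cells.get(members, 0) + 1
    return OverlapSummary(labels=labels, sets=sets, cells=cells)


def targeted_feature_sets(assignments_by_genotype:
                          Mapping[str, Sequence[DmrAssignment]],
                          kind: str = "te",
                          direction: str = "all") -> Dict[str, Set[str]]:
    """Per-genotype sets of TE ids (kind="te") or gene ids (kind="gene")
    targeted by DMRs, optionally restricted by direction."""
    out: Dict[str, Set[str]] = {}
    for genotype, assignments in assignments_by_genotype.items():
        ids: Set[str] = set()
        for a in assignments:
            if direction != "all" and a.direction != direction:
                continue
            ids.update(a.te_ids if kind == "te" else a.gene_ids)
        out[genotype] = ids
    return out
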