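"""Readers, writers and the shared genomic data model.

All internal coordinates are 0-based half-open.  The on-disk dialects keep
their native conventions: Bismark cytosine/CX reports and TAIR10-style TE
tables are 1-based inclusive, BED output is 0-based half-open.  Every reader
transparently accepts gzip-compressed input (suffix ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: column layout of a Bismark cytosine/CX report
CX_COLUMNS = ("chrom", "pos", "strand", "count_meth", "count_unmeth",
              "context", "trinucleotide")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# core data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic segment."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def context_of_trinucleotide(tri: str) -> str:
    """Methylation context implied by a cytosine's trinucleotide.

    CG when the second base is G; CHG when the third base is G (second not
    G); CHH otherwise.
    """
    if len(tri) != 3:
        raise ValueError(f"trinucleotide must have 3 bases, got {tri!r}")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class CytosineSite:
    """One strand-resolved cytosine with its read counts.

    ``pos`` is 1-based, as read from the CX report.
    """

    chrom: str
    pos: int
    strand: str
    count_meth: int
    count_unmeth: int
    context: str
    trinucleotide: str = ""

    def __post_init__(self) -> None:
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("negative read count")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.trinucleotide:
            implied = context_of_trinucleotide(self.trinucleotide)
            if implied != self.context:
                raise ValueError(
                    f"context {self.context} inconsistent with "
                    f"trinucleotide {self.trinucleotide} (implies {implied})")

    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass
class MethylomeSample:
    """A genotype/replicate's per-cytosine methylation calls.

    ``sites`` is a DataFrame with the CX-report columns, sorted by
    (chrom, pos, strand) with no duplicate key.  Zero-coverage cytosines are
    retained: they define cytosine positions but contribute no counts.
    """

    genotype: str
    replicate: str
    sites: pd.DataFrame
    genome: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in CX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sites is missing columns {missing}")
        key = df[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate site {dup.chrom}:{dup.pos}({dup.strand})")
        if not self._is_sorted(df):
            logger.info("sites for %s/%s unsorted on load; sorting",
                        self.genotype, self.replicate)
            self.sites = df.sort_values(
                ["chrom", "pos", "strand"], kind="mergesort",
                ignore_index=True)
        if not self.genome:
            self.genome = {c: int(g["pos"].max())
                           for c, g in self.sites.groupby("chrom", sort=True)}
        else:
            for chrom, g in self.sites.groupby("chrom", sort=False):
                if chrom not in self.genome:
                    raise ValueError(f"chromosome {chrom} absent from genome")
                if int(g["pos"].max()) > self.genome[chrom]:
                    raise ValueError(
                        f"site beyond end of {chrom} "
                        f"({int(g['pos'].max())} > {self.genome[chrom]})")

    @staticmethod
    def _is_sorted(df: pd.DataFrame) -> bool:
        if len(df) < 2:
            return True
        key = pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]])
        return key.is_monotonic_increasing

    @property
    def label(self) -> str:
        return f"{self.genotype}/{self.replicate}"

    def n_sites(self) -> int:
        return len(self.sites)

    def coverage(self) -> pd.Series:
        return self.sites["count_meth"] + self.sites["count_unmeth"]

    def subset_context(self, context: str) -> pd.DataFrame:
        if context == "all":
            return self.sites
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.sites[self.sites["context"] == context]


@dataclass(frozen=True)
class Gene:
    """An annotated transcriptional unit.

    ``body`` spans the first through last exon; the promoter is the 200-bp
    interval immediately upstream of the first exon on the gene's strand.
    """

    id: str
    body: GenomicInterval
    strand: str

    PROMOTER_LENGTH = 200

    def promoter(self, chrom_length: Optional[int] = None) -> Optional[GenomicInterval]:
        """200 bp upstream of the first exon, clipped at chromosome bounds.

        Returns None when the clipped interval is empty (gene starting at
        the very chromosome edge).
        """
        if self.strand == "-":
            start = self.body.end
            end = self.body.end + self.PROMOTER_LENGTH
            if chrom_length is not None:
                end = min(end, chrom_length)
        else:
            start = max(0, self.body.start - self.PROMOTER_LENGTH)
            end = self.body.start
        if start >= end:
            return None
        return GenomicInterval(self.body.chrom, start, end, self.strand)


@dataclass(frozen=True)
class TransposableElement:
    id: str
    family: str
    superfamily: str
    location: GenomicInterval

    def __post_init__(self) -> None:
        if not self.superfamily:
            raise ValueError(f"TE {self.id} has empty superfamily")


class _IntervalIndex:
    """Per-chromosome start/end arrays supporting vectorized overlap query."""

    def __init__(self, intervals: Sequence[GenomicInterval],
                 payloads: Sequence) -> None:
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, list]] = {}
        grouped: Dict[str, list] = {}
        for iv, pay in zip(intervals, payloads):
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end, pay))
        for chrom, rows in grouped.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, [r[2] for r in rows])

    def query(self, chrom: str, start: int, end: int) -> list:
        """All payloads whose interval overlaps [start, end) on chrom."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, payloads = entry
        hit = np.flatnonzero((starts < end) & (ends > start))
        return [payloads[i] for i in hit]


@dataclass
class FeatureSet:
    """Genes and TEs on a shared genome, indexed for interval queries."""

    genes: List[Gene]
    tes: List[TransposableElement]
    genome: Dict[str, int]

    def __post_init__(self) -> None:
        fam2sf: Dict[str, str] = {}
        for te in self.tes:
            sf = fam2sf.setdefault(te.family, te.superfamily)
            if sf != te.superfamily:
                raise ValueError(
                    f"family {te.family} maps to both {sf} and "
                    f"{te.superfamily}")
        self.family_to_superfamily = fam2sf
        for g in self.genes:
            self._check_bounds(g.body, g.id)
        for te in self.tes:
            self._check_bounds(te.location, te.id)
        self._gene_index = _IntervalIndex([g.body for g in self.genes],
                                          self.genes)
        self._te_index = _IntervalIndex([t.location for t in self.tes],
                                        self.tes)
        promoters = []
        prom_genes = []
        for g in self.genes:
            p = g.promoter(self.genome.get(g.body.chrom))
            if p is not None:
                promoters.append(p)
                prom_genes.append((g, p))
        self._promoter_index = _IntervalIndex(promoters, prom_genes)

    def _check_bounds(self, iv: GenomicInterval, name: str) -> None:
        length = self.genome.get(iv.chrom)
        if length is None:
            raise ValueError(f"feature {name} on unknown chromosome "
                             f"{iv.chrom}")
        if iv.end > length:
            raise ValueError(f"feature {name} extends past end of {iv.chrom}")

    def query_genes(self, chrom: str, start: int, end: int) -> List[Gene]:
        return self._gene_index.query(chrom, start, end)

    def query_tes(self, chrom: str, start: int,
                  end: int) -> List[TransposableElement]:
        return self._te_index.query(chrom, start, end)

    def query_promoters(self, chrom: str, start: int,
                        end: int) -> List[Tuple[Gene, GenomicInterval]]:
        """(gene, promoter interval) pairs overlapping the query range."""
        return self._promoter_index.query(chrom, start, end)

    def te_by_id(self) -> Dict[str, TransposableElement]:
        return {t.id: t for t in self.tes}

    def family_sizes(self) -> Dict[str, int]:
        sizes: Dict[str, int] = {}
        for te in self.tes:
            sizes[te.family] = sizes.get(te.family, 0) + 1
        return sizes


# ---------------------------------------------------------------------------
# CX reports
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cx_report(path, genotype: str = "sample",
                   replicate: str = "R1",
                   genome: Optional[Dict[str, int]] = None) -> MethylomeSample:
    """Read a Bismark cytosine/CX report into a :class:`MethylomeSample`.

    The file is tab-separated with columns chrom, pos (1-based), strand,
    methylated count, unmethylated count, context, trinucleotide.
    Zero-coverage rows are retained.  Unsorted input is sorted on load with
    a logged notice; malformed rows raise :class:`ParseError` naming the
    line number.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(CX_COLUMNS),
            dtype={"chrom": str, "strand": str, "context": str,
                   "trinucleotide": str},
            comment=None)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("pos", "count_meth", "count_unmeth"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != values.astype("Int64").astype(
            "float"))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"{path}: line {line}: non-integer value in column {col}")
        df[col] = values.astype(np.int64)
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
        token = df["context"].iloc[line - 1]
        raise ParseError(f"{path}: line {line}: unknown context {token!r}")
    bad_strand = ~df["strand"].isin(("+", "-"))
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: invalid strand")
    if (df[["pos", "count_meth", "count_unmeth"]] < 0).any().any():
        raise ParseError(f"{path}: negative position or count")
    return MethylomeSample(genotype=genotype, replicate=replicate,
                           sites=df, genome=dict(genome) if genome else {})


def write_cx_report(sample: MethylomeSample, path) -> None:
    """Write a sample back out in CX-report layout (tab-separated)."""
    with _open_text(path, "wt") as fh:
        sample.sites.to_csv(fh, sep="\t", header=False, index=False,
                            lineterminator="\n")


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3(path) -> List[Gene]:
    """Read gene models from GFF3; each gene body spans its exon extent.

    Exons are matched to genes through their Parent chain (typically
    exon → mRNA → gene).  A gene without exons falls back to the gene
    record's own span, with a warning; an exon whose parent cannot be
    resolved is skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:",
                            merge_strategy="create_unique", force=True)
    genes: List[Gene] = []
    for rec in db.features_of_type("gene"):
        exons = list(db.children(rec, featuretype="exon"))
        if exons:
            start = min(e.start for e in exons) - 1
            end = max(e.end for e in exons)
        else:
            logger.warning("gene %s has no exons; using gene record span",
                           rec.id)
            start, end = rec.start - 1, rec.end
        genes.append(Gene(id=rec.id,
                          body=GenomicInterval(rec.seqid, start, end,
                                               rec.strand),
                          strand=rec.strand))
    # exons whose Parent chain never reaches a gene record
    seen_ids = set()
    for rec in db.features_of_type("gene"):
        for e in db.children(rec, featuretype="exon"):
            seen_ids.add(e.id)
    for e in db.features_of_type("exon"):
        if e.id not in seen_ids:
            logger.warning("exon at %s:%d-%d has no resolvable gene parent; "
                           "skipped", e.seqid, e.start, e.end)
    return genes


# ---------------------------------------------------------------------------
# TE annotation table
# ---------------------------------------------------------------------------

TE_COLUMNS = ("id", "orientation", "start", "end", "family", "superfamily")


def read_te_annotation(path) -> List[TransposableElement]:
    """Read a TAIR10-style TE table.

    Tab-separated columns: TE name, orientation, start, end, family,
    superfamily; coordinates 1-based inclusive on disk, converted to
    0-based half-open internally.  The chromosome is derived from the TE
    name (``AT1TE...`` → chr1) unless a 7th column names it explicitly.
    Rows with end < start are rejected with a warning; a duplicate TE name
    is an error.
    """
    with _open_text(path) as fh:
        first = fh.readline()
    header = 0 if first and not first.split("\t")[2].strip().isdigit() else None
    df = pd.read_csv(path, sep="\t", header=header, dtype=str)
    if df.shape[1] < 6:
        raise ParseError(f"{path}: expected >= 6 tab-separated columns")
    cols = list(TE_COLUMNS) + (["chrom"] if df.shape[1] >= 7 else [])
    df = df.iloc[:, :len(cols)]
    df.columns = cols

    tes: List[TransposableElement] = []
    seen = set()
    for idx, row in df.iterrows():
        name = row["id"]
        if name in seen:
            raise ParseError(f"{path}: duplicate TE name {name!r}")
        seen.add(name)
        start1, end1 = int(row["start"]), int(row["end"])
        if end1 < start1:
            logger.warning("TE %s has end < start; record rejected", name)
            continue
        chrom = row["chrom"] if "chrom" in df.columns else _te_chrom(name)
        strand = row["orientation"]
        if strand.lower() in ("true", "false"):  # TAIR10 orientation_is_5prime
            strand = "+" if strand.lower() == "true" else "-"
        tes.append(TransposableElement(
            id=name, family=row["family"], superfamily=row["superfamily"],
            location=GenomicInterval(chrom, start1 - 1, end1, strand)))
    return tes


def _te_chrom(name: str) -> str:
    # AT1TE00010 → chr1, AT2TE... → chr2, ATMTE → chrM etc.
    if len(name) > 3 and name[:2].upper() == "AT" and "TE" in name.upper():
        return "chr" + name[2]
    raise ParseError(f"cannot derive chromosome from TE name {name!r}; "
                     "provide a 7th chromosome column")


def write_te_annotation(tes: Iterable[TransposableElement], path) -> None:
    """Write TEs in the 7-column table layout (1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(TE_COLUMNS + ("chrom",)) + "\n")
        for te in tes:
            iv = te.location
            fh.write("\t".join([
                te.id, iv.strand, str(iv.start + 1), str(iv.end),
                te.family, te.superfamily, iv.chrom]) + "\n")


# ---------------------------------------------------------------------------
# DMR BED output
# ---------------------------------------------------------------------------

def bed_score(p_value: float) -> int:
    """Phred-like BED score: round(-10*log10(p)), capped at 1000."""
    if p_value <= 0:
        return 1000
    return min(1000, round(-10.0 * math.log10(p_value)))


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED6+3: name context:direction, score from p-value,
    extra columns wt level, mutant level, n_sites."""
    with _open_text(path, "wt") as fh:
        for d in dmrs:
            iv = d.location
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                f"{d.context}:{d.direction}", str(bed_score(d.p_value)),
                ".", f"{d.wt_level:.4f}", f"{d.mut_level:.4f}",
                str(d.n_sites)]) + "\n")


def write_dmr_table(dmrs, path, params=None) -> None:
    """Full per-DMR TSV with a commented parameter header."""
    with _open_text(path, "wt") as fh:
        if params is not None:
            fh.write(f"# params: {params}\n")
        fh.write("chrom\tstart\tend\tcontext\tdirection\twt_level\t"
                 "mut_level\tn_sites\tp_value\twt_meth\twt_unmeth\t"
                 "mut_meth\tmut_unmeth\n")
        for d in dmrs:
            wm, wu, mm, mu = d.counts
            fh.write("\t".join(map(str, [
                d.location.chrom, d.location.start, d.location.end,
                d.context, d.direction, f"{d.wt_level:.6g}",
                f"{d.mut_level:.6g}", d.n_sites, f"{d.p_value:.6g}",
                wm, wu, mm, mu])) + "\n")
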