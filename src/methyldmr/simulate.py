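"""Synthetic genomes, annotations and methylomes with planted ground truth.

The generator states a small world: a single chromosome carrying
non-overlapping genes and TEs, with per-compartment baseline methylation
levels per context (TEs high in CG/CHG, low in CHH; gene bodies with CG
body methylation; intergenic background near zero), Poisson read coverage
and beta-binomial methylated counts.  Differentially methylated regions of
known coordinates and effect sizes are planted into the "mutant" methylome
so every downstream stage can be scored against truth.

Determinism: one scenario seed fans out, through ``numpy.random
.SeedSequence``, into independent child streams for feature placement,
cytosine positions, DMR planting, and each (genotype, replicate) count
draw.  Replicates and genotypes share cytosine positions — as real
methylomes of one genome do — and differ only in read counts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dmr import Dmr, HYPER, HYPO
from .io import (CONTEXTS, FeatureSet, Gene, GenomicInterval,
                 MethylomeSample, TransposableElement)

COMPARTMENTS = ("gene_body", "te_short", "te_long", "intergenic")

#: boundary between the short and long TE length modes
TE_LENGTH_SPLIT = 1000

DEFAULT_LEVELS: Dict[str, Dict[str, float]] = {
    "gene_body":  {"CG": 0.25, "CHG": 0.02, "CHH": 0.02},
    "te_short":   {"CG": 0.85, "CHG": 0.55, "CHH": 0.10},
    "te_long":    {"CG": 0.85, "CHG": 0.55, "CHH": 0.10},
    "intergenic": {"CG": 0.05, "CHG": 0.03, "CHH": 0.02},
}

#: expected cytosines per nt (both strands together), per context
DEFAULT_DENSITY = {"CG": 0.04, "CHG": 0.03, "CHH": 0.20}

DEFAULT_SUPERFAMILY_WEIGHTS = {
    "LTR/Gypsy": 0.25, "RC/Helitron": 0.20, "DNA/MuDR": 0.15,
    "DNA/Harbinger": 0.10, "LTR/Copia": 0.10, "SINE": 0.08,
    "DNA/Tc1": 0.07, "RathE1_cons": 0.05,
}

_TRINUCLEOTIDES = {"CG": ["CGA", "CGT", "CGC", "CGG"],
                   "CHG": ["CAG", "CTG", "CCG"],
                   "CHH": ["CAA", "CAT", "CTA", "CTT", "CCA", "CCT"]}


def _child_rng(seed: int, *tags) -> np.random.Generator:
    """Independent deterministic stream for one simulation stage."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, str):
            entropy.append(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
        else:
            entropy.append(int(tag) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class CompartmentModel:
    """True methylation landscape of the synthetic genome.

    ``levels[compartment][context]`` are the baseline methylation levels;
    ``dispersion`` is the beta-binomial intra-class correlation (0 means
    pure binomial counts); ``coverage_mean`` the expected reads per site;
    ``cytosine_density`` expected cytosines per nt per context, both
    strands pooled.
    """

    levels: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {c: dict(v)
                                 for c, v in DEFAULT_LEVELS.items()})
    dispersion: float = 0.02
    coverage_mean: float = 20.0
    cytosine_density: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY))

    def __post_init__(self) -> None:
        for comp, per_ctx in self.levels.items():
            for ctx, lv in per_ctx.items():
                if not 0.0 <= lv <= 1.0:
                    raise ValueError(
                        f"level {lv} for {comp}/{ctx} outside [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must be in [0, 1)")


@dataclass(frozen=True)
class PlantedDmr:
    """One planted region: where, which context, and the signed level
    shift applied in the mutant (negative = hypomethylated)."""

    interval: GenomicInterval
    context: str
    effect: float
    direction: str
    compartment: str


@dataclass
class SyntheticTruth:
    """Ground truth of a scenario: planted DMRs plus the seed that made
    them.  Planted regions are pairwise disjoint, each inside one
    compartment."""

    planted: List[PlantedDmr]
    seed: int

    def __post_init__(self) -> None:
        ivs = sorted((p.interval.chrom, p.interval.start, p.interval.end)
                     for p in self.planted)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted DMRs overlap")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _place_intervals(rng: np.random.Generator, length: int,
                     sizes: Sequence[int], occupied: List[Tuple[int, int]],
                     max_tries: int = 200) -> List[Tuple[int, int]]:
    """Place intervals of the given sizes uniformly without overlap."""
    placed: List[Tuple[int, int]] = []
    for size in sizes:
        if size >= length:
            raise ValueError(f"feature of length {size} does not fit")
        for _ in range(max_tries):
            start = int(rng.integers(0, length - size))
            end = start + size
            if all(end <= s or start >= e for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end))
                break
        else:
            raise ValueError(
                "could not place features without overlap; density too "
                "high for the requested genome length")
    return placed


def simulate_genome(length: int = 1_000_000, n_genes: int = 40,
                    n_tes: int = 80,
                    superfamily_weights: Optional[Mapping[str, float]] = None,
                    chrom: str = "chr1", seed: int = 0) -> FeatureSet:
    """Random non-overlapping gene/TE annotation on one chromosome.

    Gene bodies are 1-4 kb; TE lengths are bimodal (short 200-800 nt, long
    3-8 kb, half each in expectation).  TE families are drawn within
    superfamilies according to ``superfamily_weights``.  Deterministic
    given the seed.
    """
    rng = _child_rng(seed, "genome")
    weights = dict(superfamily_weights or DEFAULT_SUPERFAMILY_WEIGHTS)
    sf_names = sorted(weights)
    sf_p = np.array([weights[s] for s in sf_names], dtype=float)
    sf_p = sf_p / sf_p.sum()

    occupied: List[Tuple[int, int]] = []
    gene_sizes = rng.integers(1000, 4001, size=n_genes)
    gene_spans = _place_intervals(rng, length, list(gene_sizes), occupied)
    long_te = rng.random(n_tes) < 0.5
    te_sizes = np.where(long_te, rng.integers(3000, 8001, size=n_tes),
                        rng.integers(200, 801, size=n_tes))
    te_spans = _place_intervals(rng, length, list(te_sizes), occupied)

    genes = []
    for i, (start, end) in enumerate(gene_spans):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(id=f"At1g{10000 + 10 * i:05d}",
                          body=GenomicInterval(chrom, start, end, strand),
                          strand=strand))
    tes = []
    sf_draw = rng.choice(len(sf_names), size=n_tes, p=sf_p)
    for i, (start, end) in enumerate(te_spans):
        sf = sf_names[int(sf_draw[i])]
        family = f"{sf.split('/')[-1].upper()}F{int(rng.integers(1, 6))}"
        strand = "+" if rng.random() < 0.5 else "-"
        tes.append(TransposableElement(
            id=f"AT1TE{10 * i + 10:05d}", family=family, superfamily=sf,
            location=GenomicInterval(chrom, start, end, strand)))
    return FeatureSet(genes=genes, tes=tes, genome={chrom: length})


# ---------------------------------------------------------------------------
# DMR planting
# ---------------------------------------------------------------------------

def _compartment_baseline(model: CompartmentModel, compartment: str,
                          context: str) -> float:
    return model.levels[compartment][context]


def plant_dmrs(features: FeatureSet, n_regions: int = 60,
               contexts: Sequence[str] = ("CHH",),
               effect_range: Tuple[float, float] = (0.3, 0.5),
               length_range: Tuple[int, int] = (200, 400),
               te_fraction: float = 0.8,
               model: Optional[CompartmentModel] = None,
               seed: int = 0) -> SyntheticTruth:
    """Plant pairwise-disjoint DMRs of known effect into the annotation.

    Each region lands inside a single TE (with probability ``te_fraction``)
    or in intergenic space, wholly within one compartment.  The signed
    effect is drawn from ``effect_range``; when the compartment baseline
    cannot absorb the requested direction without leaving [0, 1], the
    direction is flipped so the realized |effect| always equals the
    requested magnitude.
    """
    model = model or CompartmentModel()
    rng = _child_rng(seed, "plant")
    chrom = next(iter(features.genome))
    length = features.genome[chrom]
    te_spans = sorted((t.location.start, t.location.end, t)
                      for t in features.tes
                      if t.location.chrom == chrom)
    # intergenic gaps between all features
    feature_spans = sorted(
        [(g.body.start, g.body.end) for g in features.genes
         if g.body.chrom == chrom]
        + [(t.location.start, t.location.end) for t in features.tes
           if t.location.chrom == chrom])
    gaps: List[Tuple[int, int]] = []
    prev = 0
    for s, e in feature_spans:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        gaps.append((prev, length))

    occupied: List[Tuple[int, int]] = []
    planted: List[PlantedDmr] = []
    max_tries = 200 * max(1, n_regions)
    tries = 0
    while len(planted) < n_regions:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not plant the requested number of "
                             "disjoint DMRs; lower n_regions")
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        in_te = rng.random() < te_fraction
        if in_te:
            hosts = [(s, e, t) for s, e, t in te_spans if e - s >= size]
            if not hosts:
                raise ValueError("no TE long enough to host a planted DMR")
            s, e, te = hosts[int(rng.integers(0, len(hosts)))]
            compartment = ("te_long" if e - s >= TE_LENGTH_SPLIT
                           else "te_short")
        else:
            hosts = [(s, e) for s, e in gaps if e - s >= size]
            if not hosts:
                continue
            s, e = hosts[int(rng.integers(0, len(hosts)))]
            compartment = "intergenic"
        start = int(rng.integers(s, e - size + 1))
        end = start + size
        if any(end > os and start < oe for os, oe in occupied):
            continue
        context = str(contexts[int(rng.integers(0, len(contexts)))])
        magnitude = float(rng.uniform(*effect_range))
        baseline = _compartment_baseline(model, compartment, context)
        want_hypo = rng.random() < 0.5
        if want_hypo and baseline - magnitude < 0 \
                and baseline + magnitude <= 1:
            want_hypo = False
        elif not want_hypo and baseline + magnitude > 1 \
                and baseline - magnitude >= 0:
            want_hypo = True
        effect = -magnitude if want_hypo else magnitude
        occupied.append((start, end))
        planted.append(PlantedDmr(
            interval=GenomicInterval(chrom, start, end),
            context=context, effect=effect,
            direction=HYPO if effect < 0 else HYPER,
            compartment=compartment))
    return SyntheticTruth(planted=planted, seed=seed)


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def _stab(intervals: List[Tuple[int, int]],
          positions: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted non-overlapping intervals."""
    if not intervals:
        return np.zeros(len(positions), dtype=bool)
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    ends = np.array([e for _, e in intervals], dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(positions), dtype=bool)
    inside[ok] = positions[ok] < ends[idx[ok]]
    return inside


def cytosine_positions(features: FeatureSet, model: CompartmentModel,
                       seed: int = 0) -> pd.DataFrame:
    """Deterministic cytosine landscape shared by all samples of a scenario.

    Returns one row per (chrom, pos, strand): context, trinucleotide,
    compartment, and the compartment baseline level for the site's context.
    """
    rng = _child_rng(seed, "positions")
    frames = []
    densities = model.cytosine_density
    contexts = sorted(densities)
    p = np.array([densities[c] for c in contexts], dtype=float)
    total_density = p.sum()
    if total_density > 2.0:
        raise ValueError("cytosine densities exceed 1 per strand-position")
    for chrom, length in sorted(features.genome.items()):
        n_total = int(rng.binomial(2 * length, total_density / 2.0))
        # unique (position, strand) slots
        slots = np.sort(rng.choice(2 * length, size=n_total, replace=False))
        pos0 = slots // 2
        strand = np.where(slots % 2 == 0, "+", "-")
        ctx_idx = rng.choice(len(contexts), size=n_total,
                             p=p / total_density)
        context = np.array(contexts, dtype=object)[ctx_idx]
        tri = np.empty(n_total, dtype=object)
        for i, ctx in enumerate(contexts):
            mask = ctx_idx == i
            choices = _TRINUCLEOTIDES[ctx]
            tri[mask] = np.array(choices, dtype=object)[
                rng.integers(0, len(choices), size=int(mask.sum()))]

        gene_spans = sorted((g.body.start, g.body.end)
                            for g in features.genes
                            if g.body.chrom == chrom)
        te_short = sorted((t.location.start, t.location.end)
                          for t in features.tes
                          if t.location.chrom == chrom
                          and t.location.length() < TE_LENGTH_SPLIT)
        te_long = sorted((t.location.start, t.location.end)
                         for t in features.tes
                         if t.location.chrom == chrom
                         and t.location.length() >= TE_LENGTH_SPLIT)
        compartment = np.full(n_total, "intergenic", dtype=object)
        compartment[_stab(gene_spans, pos0)] = "gene_body"
        compartment[_stab(te_short, pos0)] = "te_short"
        compartment[_stab(te_long, pos0)] = "te_long"

        level = np.empty(n_total, dtype=float)
        for comp in COMPARTMENTS:
            for ctx in contexts:
                mask = (compartment == comp) & (context == ctx)
                level[mask] = model.levels[comp][ctx]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos0 + 1, "strand": strand,
            "context": context, "trinucleotide": tri,
            "compartment": compartment, "level": level}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def _apply_truth(positions: pd.DataFrame,
                 truth: Optional[SyntheticTruth]) -> np.ndarray:
    level = positions["level"].to_numpy(dtype=float).copy()
    if truth is None:
        return level
    pos0 = positions["pos"].to_numpy(dtype=np.int64) - 1
    chrom = positions["chrom"].to_numpy()
    ctx = positions["context"].to_numpy()
    for planted in truth.planted:
        iv = planted.interval
        mask = ((chrom == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
                & (ctx == planted.context))
        level[mask] = np.clip(level[mask] + planted.effect, 0.0, 1.0)
    return level


def simulate_methylome(features: FeatureSet, model: CompartmentModel,
                       genotype: str, replicate: str,
                       truth: Optional[SyntheticTruth] = None,
                       seed: int = 0,
                       positions: Optional[pd.DataFrame] = None
                       ) -> MethylomeSample:
    """Draw one methylome: shared cytosine positions, fresh counts.

    Coverage is Poisson(``coverage_mean``); methylated counts are
    beta-binomial with intra-class correlation ``dispersion`` (binomial
    when 0) around the compartment baseline, shifted by any planted DMR
    containing the site (clipped to [0, 1]).  Pass ``truth`` only for the
    genotype that carries the planted effects.  All samples created with
    one scenario ``seed`` share positions; counts differ per
    (genotype, replicate).
    """
    if positions is None:
        positions = cytosine_positions(features, model, seed)
    rng = _child_rng(seed, "counts", genotype, replicate)
    level = _apply_truth(positions, truth)
    n = len(positions)
    coverage = rng.poisson(model.coverage_mean, size=n)
    p = level.copy()
    rho = model.dispersion
    if rho > 0:
        inner = (level > 0) & (level < 1)
        if inner.any():
            shape = (1.0 - rho) / rho
            p[inner] = rng.beta(level[inner] * shape,
                                (1.0 - level[inner]) * shape)
    meth = rng.binomial(coverage, p)
    sites = pd.DataFrame({
        "chrom": positions["chrom"].to_numpy(),
        "pos": positions["pos"].to_numpy(),
        "strand": positions["strand"].to_numpy(),
        "count_meth": meth.astype(np.int64),
        "count_unmeth": (coverage - meth).astype(np.int64),
        "context": positions["context"].to_numpy(),
        "trinucleotide": positions["trinucleotide"].to_numpy()})
    return MethylomeSample(genotype=genotype, replicate=replicate,
                           sites=sites,
                           genome=dict(features.genome))


# ---------------------------------------------------------------------------
# scenario convenience and evaluation
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully materialized synthetic experiment."""

    features: FeatureSet
    model: CompartmentModel
    truth: SyntheticTruth
    wildtype: List[MethylomeSample]
    mutant: List[MethylomeSample]


def default_scenario(seed: int = 0, genome_length: int = 1_000_000,
                     n_genes: int = 40, n_tes: int = 80,
                     n_planted: int = 60,
                     contexts: Sequence[str] = ("CHH",),
                     effect_range: Tuple[float, float] = (0.3, 0.5),
                     n_replicates: int = 2,
                     model: Optional[CompartmentModel] = None,
                     mutant_name: str = "mutant") -> Scenario:
    """The package's reference scenario: 1 Mb, 40 genes, 80 TEs, 60 planted
    CHH DMRs with |effect| in [0.3, 0.5] at 20x coverage, two replicates
    per genotype."""
    model = model or CompartmentModel()
    features = simulate_genome(genome_length, n_genes, n_tes, seed=seed)
    truth = plant_dmrs(features, n_regions=n_planted, contexts=contexts,
                       effect_range=effect_range, model=model, seed=seed)
    positions = cytosine_positions(features, model, seed)
    wildtype = [simulate_methylome(features, model, "wild-type", f"R{i+1}",
                                   truth=None, seed=seed,
                                   positions=positions)
                for i in range(n_replicates)]
    mutant = [simulate_methylome(features, model, mutant_name, f"R{i+1}",
                                 truth=truth, seed=seed,
                                 positions=positions)
              for i in range(n_replicates)]
    return Scenario(features=features, model=model, truth=truth,
                    wildtype=wildtype, mutant=mutant)


@dataclass
class CallEvaluation:
    """Recovery of planted DMRs by a set of calls."""

    sensitivity: float
    fdp: float                      # NaN when there are no calls
    n_planted: int
    n_called: int
    recovered: List[Tuple[PlantedDmr, Dmr]]
    unmatched_called: List[Dmr]


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length(), ov / b.length())


def evaluate_calls(called: Sequence[Dmr], truth: SyntheticTruth,
                   min_reciprocal_overlap: float = 0.5) -> CallEvaluation:
    """Score called DMRs against planted truth.

    A planted region is recovered iff some called DMR of the same context
    and direction reciprocally overlaps it by at least
    ``min_reciprocal_overlap``; a called DMR not matching any planted
    region counts toward the false-discovery proportion.
    """
    recovered: List[Tuple[PlantedDmr, Dmr]] = []
    matched_calls = set()
    for planted in truth.planted:
        for i, call in enumerate(called):
            if call.context != planted.context:
                continue
            if call.direction != planted.direction:
                continue
            if _reciprocal_overlap(planted.interval,
                                   call.location) >= min_reciprocal_overlap:
                recovered.append((planted, call))
                matched_calls.add(i)
                break
    unmatched = [c for i, c in enumerate(called) if i not in matched_calls]
    # a call may still legitimately overlap a planted region it did not
    # "recover" (second call on one region); only calls overlapping no
    # planted region of matching context/direction are false discoveries
    false_calls = []
    for call in unmatched:
        hit = any(call.context == p.context
                  and call.direction == p.direction
                  and _reciprocal_overlap(p.interval, call.location)
                  >= min_reciprocal_overlap
                  for p in truth.planted)
        if not hit:
            false_calls.append(call)
    n_planted = len(truth.planted)
    n_called = len(called)
    sensitivity = len(recovered) / n_planted if n_planted else float("nan")
    fdp = len(false_calls) / n_called if n_called else float("nan")
    return CallEvaluation(sensitivity=sensitivity, fdp=fdp,
                          n_planted=n_planted, n_called=n_called,
                          recovered=recovered, unmatched_called=false_calls)


# ---------------------------------------------------------------------------
# scenario output (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[Gene], path) -> None:
    """Write genes as GFF3 gene/mRNA/exon records (one exon per gene)."""
    from .io import _open_text

    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            base = (b.chrom, "methyldmr", b.start + 1, b.end, ".",
                    g.strand, ".")
            fh.write("{}\t{}\tgene\t{}\t{}\t{}\t{}\t{}\tID={}\n".format(
                *base[:2], *base[2:], g.id))
            fh.write("{}\t{}\tmRNA\t{}\t{}\t{}\t{}\t{}\tID={}.1;Parent={}\n"
                     .format(*base[:2], *base[2:], g.id, g.id))
            fh.write("{}\t{}\texon\t{}\t{}\t{}\t{}\t{}\tParent={}.1\n"
                     .format(*base[:2], *base[2:], g.id))


def write_truth(truth: SyntheticTruth, bed_path, tsv_path) -> None:
    from .io import _open_text

    with _open_text(bed_path, "wt") as fh:
        for p in truth.planted:
            fh.write("\t".join([
                p.interval.chrom, str(p.interval.start),
                str(p.interval.end), f"{p.context}:{p.direction}"]) + "\n")
    with _open_text(tsv_path, "wt") as fh:
        fh.write("chrom\tstart\tend\tcontext\tdirection\teffect\t"
                 "compartment\n")
        for p in truth.planted:
            fh.write("\t".join(map(str, [
                p.interval.chrom, p.interval.start, p.interval.end,
                p.context, p.direction, f"{p.effect:.4f}",
                p.compartment])) + "\n")
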