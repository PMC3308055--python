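"""Pedigree-realistic synthetic proband exomes.

Gene dropping: founder haplotypes are dropped through a pedigree (by default
the first-cousin structure of the study design) with crossovers drawn per
meiosis as a Poisson count at ``recombination_rate`` cM/Mb, positions
uniform, no interference, sex-averaged map.  The proband's two homologs are
then mosaics of founder haplotypes, and the maximal intervals where both
homologs descend from the *same* founder haplotype are the true autozygous
(IBD) segments — the ground truth against which ROH detection is scored.
For first-cousin parents the expected autozygous genome fraction is the
inbreeding coefficient F = 1/16.

On top of the realized diplotype, the generator emits an exome-scale variant
table (default 19,215 coding variants, coverage negative-binomial around a
mean of 37x), membership draws for a stack of known-variant reference sets,
a denser grid of genotype sites for ROH calling (homozygous inside
autozygous segments apart from a small error rate; Hardy-Weinberg zygosity
outside), and exactly one planted causal variant: novel in every reference
set, missense, homozygous, with a phyloP score far above the background
score distribution, inside an autozygous segment.  Autosomes only: the
study proband is male and hemizygous X calls would contaminate ROH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cascade import KnownVariantSet, VariantCall
from .pedigree import (
    PROBAND,
    PedigreeSpec,
    first_cousin_pedigree,
)
from .roh import GenotypeSite

__all__ = [
    "HG18_AUTOSOMES",
    "CausalSpec",
    "SimulationConfig",
    "TrueIBDSegment",
    "SimulatedExome",
    "simulate_pedigree_transmission",
    "simulate_variant_table",
    "simulate_exome",
    "write_truth",
    "read_truth",
]

#: hg18 autosome lengths in bp.
HG18_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("1", 247_249_719), ("2", 242_951_149), ("3", 199_501_827),
    ("4", 191_273_063), ("5", 180_857_866), ("6", 170_899_992),
    ("7", 158_821_424), ("8", 146_274_826), ("9", 140_273_252),
    ("10", 135_374_737), ("11", 134_452_384), ("12", 132_349_534),
    ("13", 114_142_980), ("14", 106_368_585), ("15", 100_338_915),
    ("16", 88_827_254), ("17", 78_774_742), ("18", 76_117_153),
    ("19", 63_811_651), ("20", 62_435_964), ("21", 46_944_323),
    ("22", 49_691_432),
)

KNOWN_SET_LABELS = ("snp_db", "reference_exomes", "inhouse_exome")


@dataclass(frozen=True)
class TrueIBDSegment:
    """A maximal autozygous interval (1-based inclusive) with its founder origin."""

    chrom: str
    start: int
    end: int
    founder_haplotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CausalSpec:
    """Required properties of the planted causal variant.

    The defaults plant a homozygous missense change in a ribonucleotide-
    reductase small-subunit gene with phyloP 6.741 — far above the background
    99th percentile — emulating the top-ranked candidate of a recessive
    mitochondrial-disease exome.  ``min_segment_bp`` restricts the host
    autozygous segment to ones a windowed ROH caller can recover: at the
    default site density (10/Mb) and minimum site count (25), a 5 Mb
    segment carries ~50 genotype sites, comfortably detectable.
    """

    gene: str = "RRM2B"
    amino_acid_change: str = "Pro33Ser"
    functional_class: str = "missense"
    phylop: float = 6.741
    coverage: int = 58
    min_segment_bp: int = 5_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-exome generator.

    ``novel_fraction_per_stage`` gives, per known set, the probability that a
    variant is absent from that set (draws independent across sets); the
    defaults reproduce the retention profile of a single-proband exome
    against a public SNP build (~10.5% novel), a small panel of reference
    exomes and one in-house exome.  ``phylop_*`` parameterize the background
    conservation-score mixture: a mass near zero plus an exponential tail
    above ``phylop_tail_offset``.
    """

    chromosome_lengths: tuple[tuple[str, int], ...] = HG18_AUTOSOMES
    recombination_rate: float = 1.0  # cM/Mb
    n_coding_variants: int = 19_215
    site_density: float = 10.0  # genotype sites per Mb for ROH input
    novel_fraction_per_stage: tuple[float, ...] = (0.105, 0.91, 0.73)
    known_set_labels: tuple[str, ...] = KNOWN_SET_LABELS
    functional_fraction: float = 0.443
    coverage_mean: float = 37.0
    coverage_dispersion: float = 8.0
    phylop_core_mean: float = 0.0
    phylop_core_sd: float = 0.8
    phylop_tail_weight: float = 0.15
    phylop_tail_offset: float = 2.0
    phylop_tail_scale: float = 0.8
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    het_error_in_roh: float = 0.002
    snv_fraction: float = 0.97
    causal: CausalSpec = field(default_factory=CausalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome required")
        for label, length in self.chromosome_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {label!r}: length must be positive")
        if self.n_coding_variants < 1:
            raise ValueError("n_coding_variants must be >= 1")
        if len(self.novel_fraction_per_stage) != len(self.known_set_labels):
            raise ValueError("one novel fraction per known set required")
        for name in (
            "functional_fraction",
            "het_error_in_roh",
            "snv_fraction",
            "phylop_tail_weight",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for f in self.novel_fraction_per_stage:
            if not 0 <= f <= 1:
                raise ValueError("novel fractions must be in [0, 1]")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        if self.site_density <= 0 or self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("site_density, coverage_mean, coverage_dispersion must be positive")

    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosome_lengths)

    def phylop_background_quantile(self, q: float) -> float:
        """Quantile of the background phyloP mixture (used to verify that the
        causal score clears the background 99th percentile)."""
        from scipy import stats

        if q < 1 - self.phylop_tail_weight:
            return float(
                stats.norm.ppf(
                    q / (1 - self.phylop_tail_weight),
                    loc=self.phylop_core_mean,
                    scale=self.phylop_core_sd,
                )
            )
        # Upper tail: offset + exponential.
        p_tail = (q - (1 - self.phylop_tail_weight)) / self.phylop_tail_weight
        return self.phylop_tail_offset - self.phylop_tail_scale * np.log1p(-p_tail)


# --------------------------------------------------------------------------
# Gene dropping

Mosaic = list[tuple[int, int, str]]  # (start, end, founder-haplotype label)


def _merge(mosaic: Mosaic) -> Mosaic:
    out: Mosaic = []
    for start, end, lab in mosaic:
        if out and out[-1][2] == lab and out[-1][1] + 1 == start:
            out[-1] = (out[-1][0], end, lab)
        else:
            out.append((start, end, lab))
    return out


def _slice_mosaic(mosaic: Mosaic, start: int, end: int) -> Mosaic:
    return [
        (max(s, start), min(e, end), lab)
        for s, e, lab in mosaic
        if e >= start and s <= end
    ]


def _meiosis(
    haplotypes: tuple[Mosaic, Mosaic], length: int, rate_cm_per_mb: float,
    rng: np.random.Generator,
) -> Mosaic:
    """One gamete: recombine the two parental homologs.

    Crossover count ~ Poisson(genetic length in Morgans); positions uniform.
    """
    morgans = rate_cm_per_mb * (length / 1e6) / 100.0
    n_xo = int(rng.poisson(morgans)) if morgans > 0 else 0
    if n_xo > 0:
        xo = np.sort(rng.integers(2, length + 1, size=n_xo))
        xo = np.unique(xo)
    else:
        xo = np.array([], dtype=np.int64)
    phase = int(rng.integers(0, 2))
    bounds = [1, *xo.tolist(), length + 1]
    gamete: Mosaic = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi > lo:
            gamete.extend(_slice_mosaic(haplotypes[phase], lo, hi - 1))
        phase ^= 1
    return _merge(gamete)


def simulate_pedigree_transmission(
    config: SimulationConfig,
    pedigree: PedigreeSpec | None = None,
    proband: str = PROBAND,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, tuple[Mosaic, Mosaic]], list[TrueIBDSegment]]:
    """Drop founder haplotypes through the pedigree to the proband.

    Returns the proband diplotype — per chromosome, the paternal and
    maternal homolog as founder-haplotype mosaics — and the exact maximal
    autozygous intervals (both homologs from the same founder haplotype).
    """
    if pedigree is None:
        pedigree = first_cousin_pedigree()
    if proband not in pedigree.members:
        raise KeyError(f"proband {proband!r} not in pedigree")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    depth = pedigree._topological_depths()
    order = sorted(pedigree.members, key=lambda i: (depth[i], i))

    diplotype: dict[str, tuple[Mosaic, Mosaic]] = {}
    truth: list[TrueIBDSegment] = []
    for chrom, length in config.chromosome_lengths:
        haps: dict[str, tuple[Mosaic, Mosaic]] = {}
        for ind in order:
            fa, mo = pedigree.members[ind]
            if fa is None:
                haps[ind] = (
                    [(1, length, f"{ind}.0")],
                    [(1, length, f"{ind}.1")],
                )
            else:
                haps[ind] = (
                    _meiosis(haps[fa], length, config.recombination_rate, rng),
                    _meiosis(haps[mo], length, config.recombination_rate, rng),
                )
        diplotype[chrom] = haps[proband]
        truth.extend(_ibd_segments(chrom, *haps[proband]))
    return diplotype, truth


def _ibd_segments(chrom: str, hap_a: Mosaic, hap_b: Mosaic) -> list[TrueIBDSegment]:
    """Maximal intervals where the two homologs carry the same founder label."""
    segs: list[TrueIBDSegment] = []
    i = j = 0
    current: list[int | str] | None = None  # [start, end, label]
    while i < len(hap_a) and j < len(hap_b):
        sa, ea, la = hap_a[i]
        sb, eb, lb = hap_b[j]
        lo, hi = max(sa, sb), min(ea, eb)
        if lo <= hi and la == lb:
            if current is not None and current[2] == la and current[1] + 1 == lo:
                current[1] = hi
            else:
                if current is not None:
                    segs.append(TrueIBDSegment(chrom, current[0], current[1], current[2]))
                current = [lo, hi, la]
        if ea <= eb:
            i += 1
        if eb <= ea:
            j += 1
    if current is not None:
        segs.append(TrueIBDSegment(chrom, current[0], current[1], current[2]))
    return segs


# --------------------------------------------------------------------------
# Variant table and genotype sites


def _in_segments(pos: np.ndarray, segs: list[TrueIBDSegment]) -> np.ndarray:
    """Boolean mask: which positions fall inside any (disjoint, sorted) segment."""
    if not segs:
        return np.zeros(pos.size, dtype=bool)
    starts = np.array([s.start for s in segs])
    ends = np.array([s.end for s in segs])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos[ok] <= ends[idx[ok]]
    return ok


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


def _draw_coverage(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    d = config.coverage_dispersion
    p = d / (d + config.coverage_mean)
    return np.maximum(2, rng.negative_binomial(d, p, size=n))


def _draw_phylop(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    tail = rng.random(n) < config.phylop_tail_weight
    scores = rng.normal(config.phylop_core_mean, config.phylop_core_sd, size=n)
    scores[tail] = config.phylop_tail_offset + rng.exponential(
        config.phylop_tail_scale, size=int(tail.sum())
    )
    return np.round(scores, 3)


_BASES = np.array(list("ACGT"))


def simulate_variant_table(
    diplotype: dict[str, tuple[Mosaic, Mosaic]],
    truth: list[TrueIBDSegment],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantCall], list[GenotypeSite], dict[str, KnownVariantSet], VariantCall]:
    """Emit the coding-variant table, ROH genotype sites, known sets and causal.

    Zygosity of the proband's variant calls: homozygous at every site inside
    a true autozygous segment; outside, Hardy-Weinberg given that a variant
    allele was called, i.e. P(hom | variant) = q / (2 - q) at allele
    frequency q.  Exactly one causal variant is planted inside an autozygous
    segment (chosen among those at least ``causal.min_segment_bp`` long,
    falling back to the longest) with every property the causal spec demands.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom_labels = [c for c, _ in config.chromosome_lengths]
    missing = [c for c in chrom_labels if c not in diplotype]
    if missing:
        raise ValueError(f"diplotype does not cover chromosomes: {missing}")
    lengths = np.array([l for _, l in config.chromosome_lengths], dtype=float)
    truth_by_chrom: dict[str, list[TrueIBDSegment]] = {}
    for seg in truth:
        truth_by_chrom.setdefault(seg.chrom, []).append(seg)

    # The causal variant is planted afterwards and counts toward the total.
    n_background = max(0, config.n_coding_variants - 1)
    n_per_chrom = rng.multinomial(n_background, lengths / lengths.sum())

    variants: list[VariantCall] = []
    known_keys: dict[str, set] = {lab: set() for lab in config.known_set_labels}
    qmin, qmax = config.allele_freq_range
    for (chrom, length), n_c in zip(config.chromosome_lengths, n_per_chrom):
        if n_c == 0:
            continue
        pos = _unique_positions(rng, int(n_c), length)
        n = pos.size
        q = rng.uniform(qmin, qmax, size=n)
        autoz = _in_segments(pos, truth_by_chrom.get(chrom, []))
        hom = autoz | (rng.random(n) < q / (2.0 - q))

        functional = rng.random(n) < config.functional_fraction
        fclass = np.where(
            functional,
            rng.choice(
                ["missense", "nonsense", "frameshift", "splice_site"],
                size=n, p=[0.88, 0.04, 0.04, 0.04],
            ),
            rng.choice(["synonymous", "other"], size=n, p=[0.9, 0.1]),
        )
        phylop = _draw_phylop(rng, n, config)
        cov = _draw_coverage(rng, n, config)
        reads = np.where(
            hom,
            cov - rng.binomial(cov, 0.02),
            rng.binomial(cov, 0.5),
        )
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        novel = rng.random((n, len(config.known_set_labels)))
        for k, lab in enumerate(config.known_set_labels):
            frac = config.novel_fraction_per_stage[k]
            for i in np.flatnonzero(novel[:, k] >= frac):
                known_keys[lab].add(
                    (chrom, int(pos[i]), str(_BASES[ref_i[i]]), str(_BASES[alt_i[i]]))
                )
        for i in range(n):
            variants.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref=str(_BASES[ref_i[i]]),
                    alt=str(_BASES[alt_i[i]]),
                    variant_reads=int(reads[i]),
                    coverage=int(cov[i]),
                    zygosity="hom" if hom[i] else "het",
                    gene=f"G{chrom}_{int(pos[i]) // 1_000_000}",
                    functional_class=str(fclass[i]),
                    phylop=float(phylop[i]),
                )
            )

    causal = _plant_causal(variants, truth, config, rng)

    sites = _simulate_genotype_sites(truth_by_chrom, config, rng)
    known_sets = {
        lab: KnownVariantSet(lab, frozenset(keys)) for lab, keys in known_keys.items()
    }
    return variants, sites, known_sets, causal


def _plant_causal(
    variants: list[VariantCall],
    truth: list[TrueIBDSegment],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> VariantCall:
    spec = config.causal
    if not truth:
        raise ValueError(
            "causal variant requires an autozygous segment, but the realized "
            "pedigree transmission produced none (reseed or enlarge the genome)"
        )
    eligible = [s for s in truth if s.length >= spec.min_segment_bp]
    if not eligible:
        eligible = [max(truth, key=lambda s: s.length)]
    seg = eligible[int(rng.integers(0, len(eligible)))]
    # Central half of the segment, away from boundary resolution effects.
    lo = seg.start + seg.length // 4
    hi = seg.end - seg.length // 4
    pos = int(rng.integers(lo, max(lo, hi) + 1))
    taken = {(v.chrom, v.pos) for v in variants}
    while (seg.chrom, pos) in taken:
        pos += 1
    causal = VariantCall(
        chrom=seg.chrom,
        pos=pos,
        ref="G",
        alt="A",
        variant_reads=spec.coverage,
        coverage=spec.coverage,
        zygosity="hom",
        gene=spec.gene,
        functional_class=spec.functional_class,
        phylop=spec.phylop,
        amino_acid_change=spec.amino_acid_change,
    )
    variants.append(causal)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return causal


def _simulate_genotype_sites(
    truth_by_chrom: dict[str, list[TrueIBDSegment]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[GenotypeSite]:
    sites: list[GenotypeSite] = []
    qmin, qmax = config.allele_freq_range
    for chrom, length in config.chromosome_lengths:
        n = max(1, int(round(config.site_density * length / 1e6)))
        pos = _unique_positions(rng, n, length)
        autoz = _in_segments(pos, truth_by_chrom.get(chrom, []))
        q = rng.uniform(qmin, qmax, size=pos.size)
        het_outside = rng.random(pos.size) < 2 * q * (1 - q)
        het_inside = rng.random(pos.size) < config.het_error_in_roh
        het = np.where(autoz, het_inside, het_outside)
        cov = _draw_coverage(rng, pos.size, config)
        snv = rng.random(pos.size) < config.snv_fraction
        for i in range(pos.size):
            sites.append(
                GenotypeSite(
                    chrom=chrom,
                    pos=int(pos[i]),
                    genotype_class="het" if het[i] else "hom",
                    coverage=int(cov[i]),
                    is_snv=bool(snv[i]),
                )
            )
    return sites


# --------------------------------------------------------------------------
# Bundled convenience


@dataclass
class SimulatedExome:
    """Everything one simulated proband produces."""

    config: SimulationConfig
    diplotype: dict[str, tuple[Mosaic, Mosaic]]
    truth: list[TrueIBDSegment]
    variants: list[VariantCall]
    genotype_sites: list[GenotypeSite]
    known_sets: dict[str, KnownVariantSet]
    causal: VariantCall


def simulate_exome(
    config: SimulationConfig, pedigree: PedigreeSpec | None = None
) -> SimulatedExome:
    """Run the full generator: pedigree transmission then variant table."""
    rng = np.random.default_rng(config.seed)
    diplotype, truth = simulate_pedigree_transmission(config, pedigree, rng=rng)
    variants, sites, known_sets, causal = simulate_variant_table(
        diplotype, truth, config, rng=rng
    )
    return SimulatedExome(config, diplotype, truth, variants, sites, known_sets, causal)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)


# --------------------------------------------------------------------------
# Truth serialization (BED, 0-based half-open on disk)


def write_truth(segments: list[TrueIBDSegment], path) -> None:
    from .io import write_bed

    write_bed(segments, path, name_attr="founder_haplotype")


def read_truth(path) -> list[TrueIBDSegment]:
    from .io import read_bed

    return [
        TrueIBDSegment(chrom, start, end, name)
        for chrom, start, end, name in read_bed(path)
    ]
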