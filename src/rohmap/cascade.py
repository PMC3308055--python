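"""The exclusion cascade that narrows exome variants to recessive candidates.

Starting from all coding variants, the cascade (i) subtracts variants present
in each known-variant reference set in turn (a public SNP database, a panel
of reference exomes, an in-house exome), (ii) retains putatively functional
classes (missense, nonsense, frameshift, splice site), and (iii) keeps only
variants inside runs of homozygosity.  Each stage records in/out counts so
the whole run can be reported as a filtering-summary table.

Matching against known sets is allele-aware — the key is
(chrom, pos, ref, alt) — so a novel allele at a known site survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .roh import ROHSegment

__all__ = [
    "VariantCall",
    "KnownVariantSet",
    "CascadeStage",
    "FilterCascadeReport",
    "zygosity_from_allele_fraction",
    "subtract_known",
    "keep_functional",
    "intersect_roh",
    "run_cascade",
]

FUNCTIONAL_CLASSES = frozenset({"missense", "nonsense", "frameshift", "splice_site"})
VALID_CLASSES = FUNCTIONAL_CLASSES | {"synonymous", "other"}

#: Gene-annotation delimiter for variants hitting overlapping transcripts
#: (e.g. amino-acid change "Arg2523Gln; Arg3025Gln").
GENE_DELIMITER = ";"


def zygosity_from_allele_fraction(variant_reads: int, coverage: int) -> str:
    """Classify a call from its variant-allele fraction.

    Fraction >= 0.8 is homozygous, 0.2-0.8 heterozygous, below 0.2 reference
    (returned as "ref").  These thresholds stand in for the (unpublished)
    caller heuristics and are consistent with published support columns such
    as 58/58 for a homozygote and 36/69 for a heterozygote.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive to classify zygosity")
    af = variant_reads / coverage
    if af >= 0.8:
        return "hom"
    if af >= 0.2:
        return "het"
    return "ref"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in the proband's exome (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_reads: int
    coverage: int
    zygosity: str  # "hom" | "het"
    gene: str = ""
    functional_class: str = "other"
    phylop: float | None = None
    amino_acid_change: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not 0 <= self.variant_reads <= self.coverage:
            raise ValueError(
                f"variant_reads {self.variant_reads} outside [0, coverage={self.coverage}]"
            )
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")
        if self.functional_class not in VALID_CLASSES:
            raise ValueError(f"unknown functional_class {self.functional_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_functional(self) -> bool:
        return self.functional_class in FUNCTIONAL_CLASSES

    def genes(self) -> list[str]:
        """Gene symbols, splitting multi-transcript annotations."""
        return [g.strip() for g in self.gene.split(GENE_DELIMITER) if g.strip()]


@dataclass(frozen=True)
class KnownVariantSet:
    """A reference set of known variants keyed by (chrom, pos, ref, alt)."""

    source_label: str
    keys: frozenset[tuple[str, int, str, str]]

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, VariantCall) else tuple(item)
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class CascadeStage:
    name: str
    criterion: str
    count_in: int
    count_out: int

    def __post_init__(self) -> None:
        if not 0 <= self.count_out <= self.count_in:
            raise ValueError(
                f"stage {self.name!r}: count_out {self.count_out} "
                f"outside [0, count_in={self.count_in}]"
            )


@dataclass
class FilterCascadeReport:
    """Ordered per-stage counts of the filtering cascade.

    ``homozygous_after_functional`` mirrors the homozygous sub-count reported
    alongside the functional stage; ``n_genes`` is the number of distinct
    genes among the final survivors.
    """

    stages: list[CascadeStage] = field(default_factory=list)
    homozygous_after_functional: int | None = None
    n_genes: int | None = None

    def add(self, name: str, criterion: str, count_in: int, count_out: int) -> None:
        if self.stages and count_in != self.stages[-1].count_out:
            raise ValueError(
                f"stage {name!r} count_in {count_in} != previous count_out "
                f"{self.stages[-1].count_out}"
            )
        self.stages.append(CascadeStage(name, criterion, count_in, count_out))

    def counts(self) -> list[int]:
        if not self.stages:
            return []
        return [self.stages[0].count_in] + [s.count_out for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "stages": [
                {
                    "name": s.name,
                    "criterion": s.criterion,
                    "count_in": s.count_in,
                    "count_out": s.count_out,
                }
                for s in self.stages
            ],
            "homozygous_after_functional": self.homozygous_after_functional,
            "n_genes": self.n_genes,
        }


def subtract_known(
    variants: list[VariantCall], known_set: KnownVariantSet
) -> tuple[list[VariantCall], CascadeStage]:
    """Remove variants whose (chrom, pos, ref, alt) key is in the known set."""
    survivors = [v for v in variants if v.key not in known_set.keys]
    stage = CascadeStage(
        known_set.source_label,
        f"not in {known_set.source_label}",
        len(variants),
        len(survivors),
    )
    return survivors, stage


def keep_functional(variants: list[VariantCall]) -> tuple[list[VariantCall], CascadeStage]:
    """Retain missense, nonsense, frameshift and splice-site variants."""
    survivors = [v for v in variants if v.is_functional]
    stage = CascadeStage(
        "functional",
        "missense, nonsense, frameshift or splice site",
        len(variants),
        len(survivors),
    )
    return survivors, stage


def _roh_trees(segments: list[ROHSegment]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for seg in segments:
        # IntervalTree is half-open; +1 keeps the 1-based inclusive end.
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end + 1)
    return trees


def intersect_roh(
    variants: list[VariantCall], segments: list[ROHSegment]
) -> tuple[list[VariantCall], CascadeStage]:
    """Retain variants inside an ROH segment (boundaries inclusive)."""
    trees = _roh_trees(segments)
    survivors = [
        v for v in variants if v.chrom in trees and trees[v.chrom].overlaps_point(v.pos)
    ]
    stage = CascadeStage(
        "in_roh", "in run-of-homozygosity regions", len(variants), len(survivors)
    )
    return survivors, stage


def run_cascade(
    variants: list[VariantCall],
    known_sets: list[KnownVariantSet],
    segments: list[ROHSegment],
    hom_only: bool = False,
) -> tuple[FilterCascadeReport, list[VariantCall]]:
    """Run the full exclusion cascade and report per-stage counts.

    Stage order: coding variants (input contract, logged as stage 0) ->
    known-set subtractions in the given order -> functional classes ->
    [optional homozygous-only restriction] -> ROH membership.  The homozygous
    sub-count after the functional stage is always recorded; restricting the
    cascade itself to homozygotes is opt-in (``hom_only``), since the
    reference analysis filtered by ROH membership rather than zygosity.
    """
    report = FilterCascadeReport()
    report.add("coding", "coding variants (input contract)", len(variants), len(variants))
    current = list(variants)
    for ks in known_sets:
        current, stage = subtract_known(current, ks)
        report.add(stage.name, stage.criterion, stage.count_in, stage.count_out)
    current, stage = keep_functional(current)
    report.add(stage.name, stage.criterion, stage.count_in, stage.count_out)
    report.homozygous_after_functional = sum(1 for v in current if v.zygosity == "hom")
    if hom_only:
        survivors = [v for v in current if v.zygosity == "hom"]
        report.add("homozygous", "homozygous calls only", len(current), len(survivors))
        current = survivors
    current, stage = intersect_roh(current, segments)
    report.add(stage.name, stage.criterion, stage.count_in, stage.count_out)
    report.n_genes = len({g for v in current for g in v.genes()})
    return report, current
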