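"""Candidate prioritization: conservation ranking, mitochondrial-gene
heterozygote screening, and inheritance annotation.

Cascade survivors are ranked by phyloP conservation score (higher = more
conserved = more likely functional).  Separately, heterozygous novel variants
in genes encoding mitochondrial proteins are screened as potential dominant
*de novo* candidates, and segregation observations from the parents classify
each candidate's inheritance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cascade import KnownVariantSet, VariantCall
from .roh import _chrom_sort_key

__all__ = [
    "GeneSet",
    "CandidateReport",
    "rank_by_conservation",
    "screen_mito_het",
    "annotate_inheritance",
    "make_report",
    "chromosome_count",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. nuclear-encoded mitochondrial genes)."""

    label: str
    symbols: frozenset[str]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def rank_by_conservation(variants: list[VariantCall]) -> list[VariantCall]:
    """Sort candidates by phyloP score, descending; deterministic.

    Ties (and only ties) are broken by genomic position, ascending.  A
    missing score sorts below every real score: a candidate without
    conservation evidence should not outrank scored ones.
    """

    def key(v: VariantCall):
        score = v.phylop if v.phylop is not None else float("-inf")
        return (-score, _chrom_sort_key(v.chrom), v.pos)

    return sorted(variants, key=key)


def screen_mito_het(
    variants: list[VariantCall],
    mito_genes: GeneSet,
    extra_known_sets: list[KnownVariantSet] | None = None,
    phylop_min: float = 2.0,
) -> list[VariantCall]:
    """Screen for heterozygous candidates in mitochondrial genes.

    From the novel putatively-functional variants, keep those that are
    heterozygous, lie in a gene from ``mito_genes``, are absent from every
    extra known set (e.g. a newer SNP build, population-project calls), and
    are conserved with phyloP strictly above ``phylop_min``.  These are the
    variants that could act dominantly (*de novo*) rather than recessively.
    """
    extra_known_sets = extra_known_sets or []
    out = []
    for v in variants:
        if v.zygosity != "het":
            continue
        if not any(g in mito_genes for g in v.genes()):
            continue
        if any(v.key in ks.keys for ks in extra_known_sets):
            continue
        if v.phylop is None or not v.phylop > phylop_min:
            continue
        out.append(v)
    return out


def annotate_inheritance(
    father_carrier: str,
    mother_carrier: str,
    proband_confirmed: str = "yes",
) -> str:
    """Classify inheritance from binary carrier observations.

    Observations are Sanger-style flags in {"yes", "no", "unknown"} for each
    parent, plus whether the variant itself was confirmed in the proband.
    An unconfirmed variant is a false-positive call ("not_confirmed"); a
    confirmed variant carried by a parent is inherited ("paternal",
    "maternal", or "either_parent" when both carry it); carried by neither
    parent it is a de novo candidate; otherwise evidence is incomplete.
    """
    for name, value in (
        ("father_carrier", father_carrier),
        ("mother_carrier", mother_carrier),
    ):
        if value not in ("yes", "no", "unknown"):
            raise ValueError(f"{name} must be yes/no/unknown, got {value!r}")
    if proband_confirmed not in ("yes", "no"):
        raise ValueError(f"proband_confirmed must be yes/no, got {proband_confirmed!r}")
    if proband_confirmed == "no":
        return "not_confirmed"
    if father_carrier == "yes" and mother_carrier == "yes":
        return "either_parent"
    if father_carrier == "yes":
        return "paternal"
    if mother_carrier == "yes":
        return "maternal"
    if father_carrier == "no" and mother_carrier == "no":
        return "de_novo_candidate"
    return "unknown"


REPORT_COLUMNS = [
    "rank",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_reads",
    "coverage",
    "zygosity",
    "gene",
    "amino_acid_change",
    "phylop",
    "in_mito_gene_set",
    "inheritance",
]


@dataclass
class CandidateReport:
    """Ranked candidate table with mito-gene flags and inheritance labels."""

    rows: pd.DataFrame

    @classmethod
    def build(
        cls,
        ranked: list[VariantCall],
        mito_genes: GeneSet | None = None,
        inheritance: dict[tuple[str, int, str, str], str] | None = None,
    ) -> "CandidateReport":
        inheritance = inheritance or {}
        records = []
        for rank, v in enumerate(ranked, start=1):
            records.append(
                {
                    "rank": rank,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "variant_reads": v.variant_reads,
                    "coverage": v.coverage,
                    "zygosity": v.zygosity,
                    "gene": v.gene,
                    "amino_acid_change": v.amino_acid_change,
                    "phylop": v.phylop,
                    "in_mito_gene_set": (
                        any(g in mito_genes for g in v.genes()) if mito_genes else False
                    ),
                    "inheritance": inheritance.get(v.key, "unknown"),
                }
            )
        df = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
        return cls(df)


def make_report(report: CandidateReport, tsv_path, json_path=None) -> None:
    """Write the candidate report as TSV (and optionally JSON).

    Column order is fixed; an empty candidate list yields a valid
    header-only TSV.  The JSON form is schema-versioned and reloads to the
    same ranks.
    """
    tsv_path = Path(tsv_path)
    report.rows.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "schema_version": 1,
            "candidates": report.rows.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def chromosome_count(n_subjects: int, ploidy: int = 2) -> int:
    """Number of chromosomes in a control panel of diploid subjects.

    The denominator for population allele counts, e.g. a variant seen once
    among 359 subjects is 1 of 718 chromosomes.
    """
    if n_subjects < 0:
        raise ValueError("n_subjects must be non-negative")
    return n_subjects * ploidy
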