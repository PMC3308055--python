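"""Worked-example candidate tables.

Two small published-style tables from a consanguineous arPEO (autosomal
recessive progressive external ophthalmoplegia) exome analysis, usable as
documentation examples and as fixed inputs for the ranking and screening
operations:

* ``roh_candidates()`` — the 14 scored novel, putatively functional variants
  found inside the proband's runs of homozygosity, led by the homozygous
  RRM2B Pro33Ser missense change (phyloP 6.741);
* ``mito_het_candidates()`` — the five novel, conserved (phyloP > 2)
  heterozygous variants in nuclear-encoded mitochondrial genes screened as
  potential dominant candidates, with the Sanger segregation observations
  that classify their inheritance.

Where the printed variant alleles were ambiguous, the alt alleles here are
illustrative substitutions consistent with the printed amino-acid change;
no operation in this package consults them beyond requiring ref != alt.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .cascade import VariantCall
from .prioritize import GeneSet

__all__ = ["roh_candidates", "mito_het_candidates", "MITO_GENES"]

_ROH_CANDIDATES_TSV = """\
chrom	pos	ref	alt	variant_reads	coverage	zygosity	gene	functional_class	phylop	amino_acid_change
8	103313660	G	A	58	58	hom	RRM2B	missense	6.741	Pro33Ser
1	39620317	G	A	5	7	het	MACF1	missense	5.329	Arg2523Gln; Arg3025Gln
4	107449465	A	C	63	63	hom	MGC16169	missense	5.199	Asn34Lys
22	15980313	C	T	5	5	hom	LOC100287323	missense	4.997	Val569Ile
11	64117795	G	A	4	4	hom	SLC22A12	nonsense	4.945	Trp37Stp; Trp258Stp
10	29010439	G	C	24	24	hom	BAMBI	missense	4.878	Gly108Ala
20	49482400	G	A	4	4	hom	NFATC2	missense	4.437	Ala778Val
1	238437608	C	T	10	12	hom	FMN2	missense	3.804	Pro1101Leu
1	85362528	T	-	65	69	hom	WDR63	splice_site	3.503
3	99094433	A	G	24	34	het	DKFZp667G2110	missense	3.299	Lys546Glu
3	336547	T	G	23	23	hom	CHL1	missense	3.014	Ser30Ala
3	46595758	C	G	27	40	het	LRRC2	missense	2.522	Arg41Gly
4	169335658	A	C	9	13	het	ANXA10	missense	2.257	Thr193Pro
5	140538797	C	T	127	127	hom	PCDHB8	missense	2.011	Thr333Ile
"""

_MITO_HET_TSV = """\
chrom	pos	ref	alt	variant_reads	coverage	zygosity	gene	functional_class	phylop	amino_acid_change
7	30615756	G	C	36	69	het	GARS	missense	6.494	Asp256His
10	104476790	T	C	14	30	het	SFXN2	missense	4.906	Leu73Pro
7	100670236	C	G	20	51	het	FIS1	missense	3.824	Ala90Pro
11	47620527	A	G	3	8	het	MTCH2	missense	3.680	Tyr23His
1	10286026	C	G	22	46	het	KIF1B	missense	3.092	Ile732Met
"""

#: Gene symbols of the five screened mitochondrial genes (a stand-in for a
#: full mitochondrial-proteome gene inventory).
MITO_GENES = GeneSet(
    "mito_genes", frozenset({"GARS", "SFXN2", "FIS1", "MTCH2", "KIF1B"})
)

#: Sanger-style segregation observations for the heterozygous candidates:
#: (father_carrier, mother_carrier, proband_confirmed) keyed by gene.
MITO_SEGREGATION = {
    "GARS": ("yes", "no", "yes"),
    "SFXN2": ("no", "yes", "yes"),
    "FIS1": ("no", "yes", "yes"),
    "MTCH2": ("unknown", "unknown", "no"),
    "KIF1B": ("no", "yes", "yes"),
}


def _parse(tsv: str) -> list[VariantCall]:
    df = pd.read_csv(_io.StringIO(tsv), sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for row in df.to_dict(orient="records"):
        out.append(
            VariantCall(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_reads=int(row["variant_reads"]),
                coverage=int(row["coverage"]),
                zygosity=row["zygosity"],
                gene=row["gene"],
                functional_class=row["functional_class"],
                phylop=float(row["phylop"]),
                amino_acid_change=row["amino_acid_change"],
            )
        )
    return out


def roh_candidates() -> list[VariantCall]:
    """The 14 scored novel functional variants inside the ROH segments."""
    return _parse(_ROH_CANDIDATES_TSV)


def mito_het_candidates() -> tuple[list[VariantCall], GeneSet, dict]:
    """The five heterozygous mitochondrial-gene candidates, the gene set,
    and their segregation observations."""
    return _parse(_MITO_HET_TSV), MITO_GENES, dict(MITO_SEGREGATION)
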