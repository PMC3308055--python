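"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel either as a minimal VCF dialect (INFO keys GENE,
FCLASS, PHYLOP, DP, AD, plus ZYG and AAC so a written file reloads exactly)
or as TSV.  Intervals travel as BED — 0-based half-open on disk, 1-based
inclusive in memory.  Chromosome labels are opaque strings ("chr1" and "1"
are distinct); `normalize_chrom` strips the prefix explicitly when the
caller asks for it, never silently.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .cascade import KnownVariantSet, VariantCall, zygosity_from_allele_fraction
from .mtdna import CtMeasurement
from .prioritize import GeneSet
from .roh import GenotypeSite, ROHSegment, _chrom_sort_key

__all__ = [
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_bed",
    "write_bed",
    "read_roh_bed",
    "read_known_set",
    "read_gene_set",
    "read_genotype_sites",
    "write_genotype_sites",
    "read_ct_table",
    "normalize_chrom",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_reads", "coverage",
    "zygosity", "gene", "functional_class", "phylop", "amino_acid_change",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix ("chr1" -> "1"); explicit opt-in only."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# --------------------------------------------------------------------------
# Variant tables


def _variant_from_row(row: dict, lineno: int, path) -> VariantCall:
    try:
        phylop = row.get("phylop")
        if phylop in (None, "", ".") or (isinstance(phylop, float) and math.isnan(phylop)):
            phylop = None
        else:
            phylop = float(phylop)
        aac = row.get("amino_acid_change", "")
        if aac is None or (isinstance(aac, float) and math.isnan(aac)):
            aac = ""
        return VariantCall(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            variant_reads=int(row["variant_reads"]),
            coverage=int(row["coverage"]),
            zygosity=str(row["zygosity"]),
            gene="" if pd.isna(row.get("gene")) else str(row.get("gene", "")),
            functional_class=str(row.get("functional_class", "other")),
            phylop=phylop,
            amino_acid_change=str(aac),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"{path}, line {lineno}: malformed variant row ({exc})") from exc


def read_variants(path) -> list[VariantCall]:
    """Read a variant table from minimal VCF or TSV (by extension)."""
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _read_variants_vcf(path)
    return _read_variants_tsv(path)


def _read_variants_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = [c for c in VARIANT_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        _variant_from_row(row, i + 2, path)  # +2: header is line 1
        for i, row in enumerate(df.to_dict(orient="records"))
    ]


def write_variants_tsv(variants: list[VariantCall], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "variant_reads": v.variant_reads, "coverage": v.coverage,
                "zygosity": v.zygosity, "gene": v.gene,
                "functional_class": v.functional_class,
                "phylop": "" if v.phylop is None else v.phylop,
                "amino_acid_change": v.amino_acid_change,
            }
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol(s)">
##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=PHYLOP,Number=1,Type=Float,Description="phyloP conservation score">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total coverage">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Variant-supporting reads">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity call (hom/het)">
##INFO=<ID=AAC,Number=1,Type=String,Description="Amino acid change">
"""

# VCF reserves these characters inside INFO values; percent-encode them.
_INFO_ESCAPES = {";": "%3B", "=": "%3D", ",": "%2C", " ": "%20", "%": "%25"}


def _encode_info(value: str) -> str:
    value = value.replace("%", "%25")
    for raw, enc in _INFO_ESCAPES.items():
        if raw != "%":
            value = value.replace(raw, enc)
    return value


def _decode_info(value: str) -> str:
    for raw, enc in _INFO_ESCAPES.items():
        if raw != "%":
            value = value.replace(enc, raw)
    return value.replace("%25", "%")


def write_variants_vcf(variants: list[VariantCall], path) -> None:
    """Write the minimal VCF dialect (sorted by chromosome then position)."""
    rows = sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos))
    contigs = []
    for v in rows:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in rows:
            info = (
                f"GENE={_encode_info(v.gene) or '.'}"
                f";FCLASS={v.functional_class}"
                f";PHYLOP={'.' if v.phylop is None else v.phylop}"
                f";DP={v.coverage};AD={v.variant_reads};ZYG={v.zygosity}"
            )
            if v.amino_acid_change:
                info += f";AAC={_encode_info(v.amino_acid_change)}"
            alt = v.alt if v.alt else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{alt}\t.\t.\t{info}\n"
            )


def _read_variants_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    out: list[VariantCall] = []
    for rec in VCF(str(path)):
        coverage = int(rec.INFO.get("DP", 0))
        reads = int(rec.INFO.get("AD", 0))
        zyg = rec.INFO.get("ZYG")
        if zyg is None:
            # Derive from the allele fraction (>= 0.8 => homozygous).
            zyg = "hom" if zygosity_from_allele_fraction(reads, coverage) == "hom" else "het"
        phylop = rec.INFO.get("PHYLOP")
        gene = rec.INFO.get("GENE")
        aac = rec.INFO.get("AAC", "") or ""
        out.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else "",
                variant_reads=reads,
                coverage=coverage,
                zygosity=str(zyg),
                gene="" if gene in (None, ".") else _decode_info(str(gene)),
                functional_class=str(rec.INFO.get("FCLASS", "other")),
                phylop=None if phylop is None else round(float(phylop), 6),
                amino_acid_change=_decode_info(str(aac)),
            )
        )
    return out


# --------------------------------------------------------------------------
# BED intervals


def write_bed(segments, path, name_attr: str | None = None) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start)."""
    rows = sorted(segments, key=lambda s: (_chrom_sort_key(s.chrom), s.start))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend" + ("\tname\n" if name_attr else "\n"))
        for seg in rows:
            line = f"{seg.chrom}\t{seg.start - 1}\t{seg.end}"
            if name_attr:
                line += f"\t{getattr(seg, name_attr)}"
            fh.write(line + "\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED into (chrom, start, end, name) tuples, 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start + 1, end, name))
    return out


def read_roh_bed(path) -> list[ROHSegment]:
    return [
        ROHSegment(chrom, start, end, n_sites=max(1, int(name) if name.isdigit() else 1))
        for chrom, start, end, name in read_bed(path)
    ]


def write_roh_bed(segments: list[ROHSegment], path) -> None:
    write_bed(segments, path, name_attr="n_sites")


# --------------------------------------------------------------------------
# Known-variant sets, gene sets, genotype sites, Ct tables


def read_known_set(path, label: str | None = None) -> KnownVariantSet:
    """Read a known-variant set: TSV with columns chrom, pos, ref, alt."""
    path = Path(path)
    keys = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["chrom", "pos"]:  # optional header
                continue
            if len(fields) < 4:
                raise ValueError(
                    f"{path}, line {lineno}: expected chrom/pos/ref/alt, got {len(fields)} fields"
                )
            try:
                keys.add((fields[0], int(fields[1]), fields[2], fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return KnownVariantSet(label or path.stem, frozenset(keys))


def write_known_set(known: KnownVariantSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(
            known.keys, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3])
        ):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """One gene symbol per line; '#' lines are comments."""
    path = Path(path)
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    return GeneSet(label or path.stem, frozenset(symbols))


SITE_COLUMNS = ["chrom", "pos", "genotype_class", "coverage", "is_snv"]


def read_genotype_sites(path) -> list[GenotypeSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            out.append(
                GenotypeSite(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    genotype_class=str(row["genotype_class"]),
                    coverage=int(row["coverage"]),
                    is_snv=bool(row["is_snv"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return out


def write_genotype_sites(sites: list[GenotypeSite], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom, "pos": s.pos, "genotype_class": s.genotype_class,
                "coverage": s.coverage, "is_snv": s.is_snv,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> list[CtMeasurement]:
    """Long-format qPCR table: sample, target, reaction, ct (one well per row)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "target": str, "reaction": str})
    missing = [c for c in ("sample", "target", "reaction", "ct") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    grouped = df.groupby(["sample", "target", "reaction"], sort=True)["ct"]
    return [
        CtMeasurement(sample, target, str(reaction), tuple(float(c) for c in cts))
        for (sample, target, reaction), cts in grouped
    ]
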