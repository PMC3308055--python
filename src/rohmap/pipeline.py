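"""End-to-end pipeline: genotype QC -> ROH -> cascade -> ranking -> screens.

`analyze` is the in-memory engine; `run_pipeline` wraps it with file I/O
driven by a `PipelineConfig` (loadable from YAML) and writes every report
to the output directory.  Every stage's counts are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .cascade import FilterCascadeReport, KnownVariantSet, VariantCall, run_cascade
from .prioritize import (
    CandidateReport,
    GeneSet,
    make_report,
    rank_by_conservation,
    screen_mito_het,
)
from .roh import (
    GENOME_LENGTH_HG18,
    GenotypeSite,
    ROHParams,
    ROHSegment,
    detect_roh,
    filter_genotypes_for_roh,
    summarize_roh,
)

logger = logging.getLogger("rohmap")

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    n_sites_input: int
    n_sites_qc: int
    roh_segments: list[ROHSegment]
    roh_total_bp: int
    roh_fraction: float
    cascade_report: FilterCascadeReport
    survivors: list[VariantCall]
    ranked: list[VariantCall]
    candidates: CandidateReport
    mito_screen: list[VariantCall] | None = None


def analyze(
    variants: list[VariantCall],
    genotype_sites: list[GenotypeSite],
    known_sets: list[KnownVariantSet],
    roh_params: ROHParams | None = None,
    genome_length: int = GENOME_LENGTH_HG18,
    hom_only: bool = False,
    mito_genes: GeneSet | None = None,
    extra_known_sets: list[KnownVariantSet] | None = None,
    phylop_min: float = 2.0,
) -> PipelineResult:
    """Run QC, ROH detection, the exclusion cascade and conservation ranking.

    When ``mito_genes`` is given, the heterozygous mitochondrial-gene screen
    is additionally applied to the novel functional variants (the cascade
    survivors before ROH restriction).
    """
    qc_sites = filter_genotypes_for_roh(genotype_sites)
    logger.info("genotype QC: %d -> %d sites", len(genotype_sites), len(qc_sites))
    segments = detect_roh(qc_sites, roh_params)
    total_bp, fraction = summarize_roh(segments, genome_length)
    logger.info(
        "ROH: %d segments, %.1f Mb (%.1f%% of genome)",
        len(segments), total_bp / 1e6, 100 * fraction,
    )
    report, survivors = run_cascade(variants, known_sets, segments, hom_only=hom_only)
    for stage in report.stages:
        logger.info("cascade %-18s %6d -> %6d", stage.name, stage.count_in, stage.count_out)
    ranked = rank_by_conservation(survivors)

    mito_screen = None
    if mito_genes is not None:
        # Novel functional variants (pre-ROH) are the screen's input pool.
        pool = variants
        for ks in known_sets:
            pool = [v for v in pool if v.key not in ks.keys]
        pool = [v for v in pool if v.is_functional]
        mito_screen = screen_mito_het(pool, mito_genes, extra_known_sets, phylop_min)
        logger.info("mito het screen: %d candidates", len(mito_screen))

    candidates = CandidateReport.build(ranked, mito_genes)
    return PipelineResult(
        n_sites_input=len(genotype_sites),
        n_sites_qc=len(qc_sites),
        roh_segments=segments,
        roh_total_bp=total_bp,
        roh_fraction=fraction,
        cascade_report=report,
        survivors=survivors,
        ranked=ranked,
        candidates=candidates,
        mito_screen=mito_screen,
    )


@dataclass
class PipelineConfig:
    """File-level configuration of a full pipeline run."""

    variants: str
    genotype_sites: str
    known_sets: list[str]
    outdir: str
    mito_genes: str | None = None
    extra_known_sets: list[str] = field(default_factory=list)
    roh_params: dict = field(default_factory=dict)
    genome_length: int = GENOME_LENGTH_HG18
    hom_only: bool = False
    phylop_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.known_sets:
            raise ValueError("at least one known-variant set is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured pipeline and write all reports to ``outdir``."""

    def _load(stage: str, loader, path):
        if not Path(path).exists():
            raise FileNotFoundError(f"stage {stage!r}: input not found: {path}")
        try:
            return loader(path)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed on {path}: {exc}") from exc

    variants = _load("read_variants", rio.read_variants, config.variants)
    sites = _load("read_genotype_sites", rio.read_genotype_sites, config.genotype_sites)
    known = [_load("read_known_set", rio.read_known_set, p) for p in config.known_sets]
    extra = [_load("read_known_set", rio.read_known_set, p) for p in config.extra_known_sets]
    mito = (
        _load("read_gene_set", rio.read_gene_set, config.mito_genes)
        if config.mito_genes
        else None
    )

    result = analyze(
        variants,
        sites,
        known,
        ROHParams(**config.roh_params),
        genome_length=config.genome_length,
        hom_only=config.hom_only,
        mito_genes=mito,
        extra_known_sets=extra or None,
        phylop_min=config.phylop_min,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_roh_bed(result.roh_segments, outdir / "roh_segments.bed")
    rio.write_variants_tsv(result.survivors, outdir / "survivors.tsv")
    make_report(result.candidates, outdir / "candidates.tsv", outdir / "candidates.json")
    cascade_json = result.cascade_report.to_dict()
    cascade_json["roh_total_bp"] = result.roh_total_bp
    cascade_json["roh_fraction"] = result.roh_fraction
    (outdir / "cascade_report.json").write_text(json.dumps(cascade_json, indent=2) + "\n")
    if result.mito_screen is not None:
        rio.write_variants_tsv(result.mito_screen, outdir / "mito_het_screen.tsv")
    return result
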