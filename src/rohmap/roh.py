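"""Run-of-homozygosity (ROH) detection from genotype calls.

Genotype calls are first quality-gated (SNVs only, coverage between 8x and
100x inclusive; indels and high-coverage sites are unreliable or map to
duplicated regions).  Detection then follows a sliding-window scheme in the
PLINK tradition, simplified to site-anchored windows:

* one window of ``window_kb`` is anchored at every site, spanning
  ``[pos, pos + window - 1]``;
* a window is *homozygous* if it contains at most ``max_het_per_window``
  heterozygous calls;
* each site's hit fraction is the proportion of windows covering it that are
  homozygous; sites whose fraction reaches ``min_hom_window_fraction`` are
  ROH-supporting;
* maximal runs of consecutive supporting sites — broken by any
  non-supporting site or by an inter-site gap above ``max_gap_kb`` — become
  segments when they span at least ``min_segment_kb`` and contain at least
  ``min_sites`` sites.

The defaults are deliberately permissive ("relaxed criteria"): the purpose
of ROH mapping here is to avoid overlooking the causal region in a
consanguineous proband, not to delimit autozygosity precisely, so the
realized ROH total typically overshoots the pedigree expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenotypeSite",
    "ROHParams",
    "ROHSegment",
    "GENOME_LENGTH_HG18",
    "filter_genotypes_for_roh",
    "detect_roh",
    "summarize_roh",
]

#: Sum of hg18 autosome lengths, the denominator for genome-fraction
#: reporting (overridable wherever it is used).
GENOME_LENGTH_HG18 = 3_080_000_000


@dataclass(frozen=True)
class GenotypeSite:
    """One genotype call used as ROH input (1-based position)."""

    chrom: str
    pos: int
    genotype_class: str  # "hom" | "het"
    coverage: int
    is_snv: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if self.genotype_class not in ("hom", "het"):
            raise ValueError(f"genotype_class must be hom/het, got {self.genotype_class!r}")


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters (all sizes in kb)."""

    window_kb: float = 1000.0
    max_het_per_window: int = 1
    min_hom_window_fraction: float = 0.05
    min_segment_kb: float = 1000.0
    min_sites: int = 25
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("window_kb", "min_segment_kb", "min_sites", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_window < 0:
            raise ValueError("max_het_per_window must be >= 0")
        if not 0 < self.min_hom_window_fraction <= 1:
            raise ValueError("min_hom_window_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """A homozygous segment; coordinates 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


MIN_ROH_COVERAGE = 8
MAX_ROH_COVERAGE = 100


def filter_genotypes_for_roh(
    sites: list[GenotypeSite],
    min_coverage: int = MIN_ROH_COVERAGE,
    max_coverage: int = MAX_ROH_COVERAGE,
) -> list[GenotypeSite]:
    """Quality gate: keep SNVs with min_coverage <= coverage <= max_coverage.

    Calls below 8x are unreliable; calls above 100x tend to come from
    duplicated regions or pseudogenes.  Both bounds are inclusive on the kept
    side (coverage "less than 8" and "more than 100" are excluded).  Indel
    calls are dropped regardless of coverage.  Input order is preserved.
    """
    return [
        s for s in sites if s.is_snv and min_coverage <= s.coverage <= max_coverage
    ]


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural order for chromosome labels: chr2 < chr10, '1' < '2' < 'X'."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body), "") if body.isdigit() else (1, 0, body)


def _detect_one_chrom(
    pos: np.ndarray, het: np.ndarray, chrom: str, params: ROHParams
) -> list[ROHSegment]:
    window = int(round(params.window_kb * 1000))
    max_gap = int(round(params.max_gap_kb * 1000))
    min_len = int(round(params.min_segment_kb * 1000))
    n = pos.size
    if n == 0:
        return []

    # Window anchored at site j spans [pos[j], pos[j] + window - 1].
    het_cum = np.concatenate(([0], np.cumsum(het)))
    right = np.searchsorted(pos, pos + window - 1, side="right")
    win_hom = (het_cum[right] - het_cum[np.arange(n)]) <= params.max_het_per_window

    # Site s is covered by windows anchored at j with pos[s]-window+1 <= pos[j] <= pos[s].
    hom_cum = np.concatenate(([0], np.cumsum(win_hom)))
    lo = np.searchsorted(pos, pos - window + 1, side="left")
    hi = np.arange(1, n + 1)  # anchors at indices <= s (pos sorted)
    n_cov = hi - lo
    n_hom = hom_cum[hi] - hom_cum[lo]
    supporting = (n_hom / n_cov) >= params.min_hom_window_fraction

    # Maximal runs of supporting sites, broken by gaps > max_gap.
    segments: list[ROHSegment] = []
    idx = np.flatnonzero(supporting)
    if idx.size == 0:
        return []
    gap_break = np.diff(pos[idx]) > max_gap
    nonconsec = np.diff(idx) > 1  # an intervening non-supporting site
    breaks = np.flatnonzero(gap_break | nonconsec) + 1
    for run in np.split(idx, breaks):
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        if end - start + 1 >= min_len and run.size >= params.min_sites:
            segments.append(ROHSegment(chrom, start, end, int(run.size)))
    return segments


def detect_roh(sites: list[GenotypeSite], params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments from quality-gated genotype calls.

    ``sites`` must be grouped by chromosome with positions sorted ascending
    within each chromosome (ties allowed; exact duplicate positions are
    deduplicated, keeping a heterozygous call if the duplicates disagree).
    Returns disjoint segments sorted by (chromosome, start); segment
    boundaries are the first and last supporting site positions.
    """
    if params is None:
        params = ROHParams()
    by_chrom: dict[str, list[GenotypeSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    segments: list[ROHSegment] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        grp = by_chrom[chrom]
        pos = np.array([s.pos for s in grp], dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"sites on {chrom} are not sorted by position")
        het = np.array([s.genotype_class == "het" for s in grp], dtype=np.int64)
        # Deduplicate identical positions; a site is het if any duplicate is.
        if pos.size and np.any(np.diff(pos) == 0):
            uniq, inv = np.unique(pos, return_inverse=True)
            het_u = np.zeros(uniq.size, dtype=np.int64)
            np.maximum.at(het_u, inv, het)
            pos, het = uniq, het_u
        segments.extend(_detect_one_chrom(pos, het, chrom, params))
    return segments


def summarize_roh(
    segments: list[ROHSegment], genome_length_bp: int = GENOME_LENGTH_HG18
) -> tuple[int, float]:
    """Total ROH length (bp) and its fraction of the genome.

    Segments must be disjoint within each chromosome; overlap is rejected
    because it would double-count bases.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")
    total = sum(seg.length for seg in segments)
    return total, total / genome_length_bp
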