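"""Relative mtDNA copy number from real-time quantitative PCR.

Copy numbers of a nuclear reference gene (RNaseP) and two mitochondrial
genes (ND1, ND4) are compared via threshold cycles:

    ratio = 2 ** (Ct_RNaseP - Ct_gene)

so one cycle earlier means twice the template.  ND1 lies outside and ND4
inside the region removed by the common large mtDNA deletions, so the
deletion index ND4/ND1 drops below 1 when deleted molecules accumulate,
while the ND1/RNaseP ratio reflects total mtDNA copy number (depletion
when low).

Replicate structure: each sample is measured in independent reactions, each
reaction running replicate wells per target.  Cts are averaged within a
reaction, converted to per-reaction ratios, and the ratios averaged across
reactions.  Sample ratios are finally normalized to the arithmetic mean of
the control samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean

__all__ = [
    "TARGETS",
    "CtMeasurement",
    "MtDNAReport",
    "relative_copy_number",
    "aggregate_sample",
    "normalize_to_controls",
]

NUCLEAR_REFERENCE = "RNaseP"
MT_TARGETS = ("ND1", "ND4")
TARGETS = (NUCLEAR_REFERENCE,) + MT_TARGETS


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate threshold cycles for one (sample, target, reaction)."""

    sample: str
    target: str
    reaction: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if len(self.cts) < 1:
            raise ValueError("at least one replicate Ct required")
        for ct in self.cts:
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"Ct values must be finite and > 0, got {ct}")


@dataclass
class MtDNAReport:
    """Per-sample copy-number ratios and deletion index."""

    sample: str
    nd1_ratio: float | None
    nd4_ratio: float | None
    deletion_index: float | None = field(init=False)
    nd1_normalized: float | None = None
    nd4_normalized: float | None = None

    def __post_init__(self) -> None:
        if self.nd1_ratio is not None and self.nd4_ratio is not None:
            self.deletion_index = self.nd4_ratio / self.nd1_ratio
        else:
            self.deletion_index = None


def relative_copy_number(ct_target: float, ct_ref: float) -> float:
    """Copy number of the target relative to the reference: 2**(ct_ref - ct_target)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_ref - ct_target)


def aggregate_sample(measurements: list[CtMeasurement]) -> MtDNAReport:
    """Aggregate one sample's measurements into copy-number ratios.

    Within each reaction, replicate Cts are averaged per target and the
    per-reaction ratio computed against the nuclear reference; ratios are
    then averaged across reactions.  Every reaction must include the nuclear
    reference.  A mitochondrial target absent from all reactions is reported
    as ``None``, never fabricated.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    samples = {m.sample for m in measurements}
    if len(samples) != 1:
        raise ValueError(f"measurements span multiple samples: {sorted(samples)}")
    (sample,) = samples

    by_reaction: dict[str, dict[str, float]] = {}
    for m in measurements:
        mean_ct = mean(m.cts)
        targets = by_reaction.setdefault(m.reaction, {})
        if m.target in targets:
            raise ValueError(
                f"duplicate target {m.target!r} in reaction {m.reaction!r}"
            )
        targets[m.target] = mean_ct

    ratios: dict[str, list[float]] = {t: [] for t in MT_TARGETS}
    for reaction, targets in by_reaction.items():
        if NUCLEAR_REFERENCE not in targets:
            raise ValueError(f"reaction {reaction!r} lacks {NUCLEAR_REFERENCE}")
        for t in MT_TARGETS:
            if t in targets:
                ratios[t].append(
                    relative_copy_number(targets[t], targets[NUCLEAR_REFERENCE])
                )

    return MtDNAReport(
        sample=sample,
        nd1_ratio=mean(ratios["ND1"]) if ratios["ND1"] else None,
        nd4_ratio=mean(ratios["ND4"]) if ratios["ND4"] else None,
    )


def normalize_to_controls(
    reports: list[MtDNAReport], control_samples: list[str]
) -> list[MtDNAReport]:
    """Express each ratio relative to the arithmetic mean of the controls.

    After normalization the control mean is exactly 1 for each target.
    """
    if not control_samples:
        raise ValueError("at least one control sample required")
    by_sample = {r.sample: r for r in reports}
    missing = [c for c in control_samples if c not in by_sample]
    if missing:
        raise ValueError(f"control samples absent from reports: {missing}")

    for attr in ("nd1_ratio", "nd4_ratio"):
        values = [getattr(by_sample[c], attr) for c in control_samples]
        if any(v is None for v in values):
            raise ValueError(f"control sample missing {attr}")
        ctrl_mean = mean(values)
        for r in reports:
            v = getattr(r, attr)
            setattr(
                r,
                attr.replace("_ratio", "_normalized"),
                None if v is None else v / ctrl_mean,
            )
    return reports
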