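"""Exclusion cascade: allele-aware subtraction, functional filter, ROH
intersection (vs brute force), chain consistency."""

import numpy as np
import pytest

from rohmap import (
    KnownVariantSet,
    ROHSegment,
    VariantCall,
    intersect_roh,
    keep_functional,
    run_cascade,
    subtract_known,
    zygosity_from_allele_fraction,
)
from rohmap.datasets import roh_candidates


def vc(chrom="1", pos=100, ref="A", alt="G", zyg="hom", fclass="missense", **kw):
    kw.setdefault("variant_reads", 20)
    kw.setdefault("coverage", 20)
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, zygosity=zyg,
        functional_class=fclass, **kw,
    )


class TestSubtractKnown:
    def test_allele_aware_matching(self):
        known = KnownVariantSet("db", frozenset({("1", 100, "A", "G")}))
        same = vc(alt="G")
        other_alt = vc(alt="T")
        survivors, stage = subtract_known([same, other_alt], known)
        assert survivors == [other_alt]
        assert (stage.count_in, stage.count_out) == (2, 1)

    def test_empty_set_is_identity(self):
        variants = [vc(pos=p) for p in (1, 2, 3)]
        survivors, _ = subtract_known(variants, KnownVariantSet("db", frozenset()))
        assert survivors == variants


class TestKeepFunctional:
    def test_synonymous_removed(self):
        survivors, _ = keep_functional([vc(fclass="synonymous"), vc(fclass="other")])
        assert survivors == []

    def test_all_published_candidate_rows_are_functional(self):
        rows = roh_candidates()
        survivors, stage = keep_functional(rows)
        assert survivors == rows
        assert stage.count_out == 14

    def test_empty_input(self):
        assert keep_functional([]) == ([], keep_functional([])[1])


class TestIntersectROH:
    def test_boundaries_inclusive(self):
        seg = ROHSegment("1", 100, 200, 5)
        inside = [vc(pos=100), vc(pos=200), vc(pos=150)]
        outside = [vc(pos=99), vc(pos=201)]
        survivors, _ = intersect_roh(inside + outside, [seg])
        assert survivors == inside

    def test_chromosome_without_segment(self):
        survivors, _ = intersect_roh([vc(chrom="2")], [ROHSegment("1", 1, 10**7, 5)])
        assert survivors == []

    def test_matches_all_pairs_containment_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            variants = [
                vc(chrom=str(rng.integers(1, 4)), pos=int(rng.integers(1, 10_000)))
                for _ in range(40)
            ]
            segs = []
            for _ in range(rng.integers(0, 8)):
                start = int(rng.integers(1, 9_000))
                segs.append(
                    ROHSegment(str(rng.integers(1, 4)), start, start + int(rng.integers(0, 2_000)), 1)
                )
            survivors, _ = intersect_roh(variants, segs)
            expected = [
                v
                for v in variants
                if any(s.chrom == v.chrom and s.start <= v.pos <= s.end for s in segs)
            ]
            assert survivors == expected


class TestRunCascade:
    def make_inputs(self):
        known = KnownVariantSet("db", frozenset({("1", 1, "A", "G")}))
        segs = [ROHSegment("1", 1, 1_000, 3)]
        variants = [
            vc(pos=1),                      # known
            vc(pos=2),                      # novel, functional, in ROH, hom
            vc(pos=3, zyg="het"),           # novel, functional, in ROH, het
            vc(pos=4, fclass="synonymous"), # novel, not functional
            vc(pos=5_000),                  # novel, functional, outside ROH
        ]
        return variants, [known], segs

    def test_counts_monotone_and_chained(self):
        variants, known, segs = self.make_inputs()
        report, survivors = run_cascade(variants, known, segs)
        counts = report.counts()
        assert counts == sorted(counts, reverse=True)
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert nxt.count_in == prev.count_out
        assert {v.pos for v in survivors} == {2, 3}
        # functional survivors are pos 2 (hom), 3 (het), 5000 (hom)
        assert report.homozygous_after_functional == 2
        assert report.n_genes is not None and report.n_genes <= len(survivors)

    def test_all_known_input_still_reports_every_stage(self):
        variants = [vc(pos=1)]
        known = [KnownVariantSet("db", frozenset({("1", 1, "A", "G")}))]
        report, survivors = run_cascade(variants, known, [])
        assert survivors == []
        # stage 0 + one subtraction + functional + ROH
        assert [s.name for s in report.stages] == ["coding", "db", "functional", "in_roh"]
        assert report.stages[-1].count_out == 0

    def test_hom_only_flag_drops_heterozygotes(self):
        variants, known, segs = self.make_inputs()
        _, survivors = run_cascade(variants, known, segs, hom_only=True)
        assert {v.pos for v in survivors} == {2}

    def test_subtraction_order_does_not_change_survivors(self):
        rng = np.random.default_rng(3)
        variants = [vc(pos=int(p)) for p in rng.choice(10_000, 200, replace=False)]
        sets = [
            KnownVariantSet(
                lab,
                frozenset(
                    v.key for v in variants if rng.random() < p
                ),
            )
            for lab, p in (("a", 0.5), ("b", 0.3), ("c", 0.2))
        ]
        segs = [ROHSegment("1", 1, 10_000, 5)]
        _, fwd = run_cascade(variants, sets, segs)
        _, rev = run_cascade(variants, sets[::-1], segs)
        assert fwd == rev

    def test_no_survivor_in_any_known_set_and_all_in_roh(self):
        variants, known, segs = self.make_inputs()
        _, survivors = run_cascade(variants, known, segs)
        for v in survivors:
            assert all(v.key not in ks.keys for ks in known)
            assert any(s.chrom == v.chrom and s.start <= v.pos <= s.end for s in segs)


class TestZygosityFromAlleleFraction:
    @pytest.mark.parametrize(
        "reads, cov, expected",
        [(58, 58, "hom"), (48, 60, "hom"), (36, 69, "het"), (12, 60, "het"), (5, 60, "ref")],
    )
    def test_thresholds(self, reads, cov, expected):
        assert zygosity_from_allele_fraction(reads, cov) == expected

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariantCall("1", 1, "A", "A", 1, 2, "hom")
        with pytest.raises(ValueError):
            VariantCall("1", 1, "A", "G", 5, 2, "hom")
        with pytest.raises(ValueError):
            VariantCall("1", 0, "A", "G", 1, 2, "hom")
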