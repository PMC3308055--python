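"""Pedigree structures, kinship recursion and expected autozygosity.

The inbreeding coefficient F of an individual — the probability that a random
autosomal locus carries two alleles identical by descent — equals the kinship
coefficient of the parents.  Kinship is computed exactly (as a rational
number) with the classic recursion

    phi(i, i) = 1/2 * (1 + phi(father_i, mother_i))
    phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j))   [i not ancestor of j]

with founders unrelated: phi(f, f) = 1/2 and phi(f, g) = 0 for distinct
founders.  For offspring of first cousins F = 1/16, i.e. one sixteenth of the
autosomal genome is expected to be autozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

__all__ = [
    "PedigreeSpec",
    "first_cousin_pedigree",
    "unrelated_parents_pedigree",
    "kinship",
    "expected_inbreeding",
]


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree as a mapping of member id -> (father, mother).

    Founders map to ``(None, None)``; every non-founder names exactly two
    parents that are themselves members.  The structure must be acyclic.
    """

    members: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, (fa, mo) in self.members.items():
            if (fa is None) != (mo is None):
                raise ValueError(f"{ind!r}: must have two parents or be a founder")
            for p in (fa, mo):
                if p is not None and p not in self.members:
                    raise ValueError(f"{ind!r}: parent {p!r} not in pedigree")
        self._topological_depths()  # raises on cycles

    def is_founder(self, ind: str) -> bool:
        return self.members[ind] == (None, None)

    def founders(self) -> list[str]:
        return [i for i in self.members if self.is_founder(i)]

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        try:
            return self.members[ind]
        except KeyError:
            raise KeyError(f"individual {ind!r} not in pedigree") from None

    def _topological_depths(self) -> dict[str, int]:
        """Generation depth per member (founders = 0); detects cycles."""
        depth: dict[str, int] = {}

        def rec(ind: str, stack: frozenset[str]) -> int:
            if ind in depth:
                return depth[ind]
            if ind in stack:
                raise ValueError(f"pedigree cycle through {ind!r}")
            fa, mo = self.members[ind]
            if fa is None:
                d = 0
            else:
                d = 1 + max(rec(fa, stack | {ind}), rec(mo, stack | {ind}))
            depth[ind] = d
            return d

        for ind in self.members:
            rec(ind, frozenset())
        return depth


#: Members of the built-in first-cousin pedigree (proband's parents are
#: children of two full siblings who share the grandparental founder couple).
PROBAND = "proband"
FATHER = "father"
MOTHER = "mother"


def first_cousin_pedigree() -> PedigreeSpec:
    """The study pedigree: a proband born of a first-cousin marriage.

    One shared founder couple (the proband's shared great-grandparents),
    their two children (siblings) married to unrelated founders, and the two
    resulting first cousins married to each other.
    """
    return PedigreeSpec(
        {
            "ggf": (None, None),
            "ggm": (None, None),
            "sib1_spouse": (None, None),
            "sib2_spouse": (None, None),
            "sib1": ("ggf", "ggm"),
            "sib2": ("ggf", "ggm"),
            FATHER: ("sib1", "sib1_spouse"),
            MOTHER: ("sib2", "sib2_spouse"),
            PROBAND: (FATHER, MOTHER),
        }
    )


def unrelated_parents_pedigree() -> PedigreeSpec:
    """Outbred control pedigree: both parents are founders."""
    return PedigreeSpec(
        {
            FATHER: (None, None),
            MOTHER: (None, None),
            PROBAND: (FATHER, MOTHER),
        }
    )


def kinship(pedigree: PedigreeSpec, a: str, b: str) -> Fraction:
    """Exact kinship coefficient phi(a, b) between two pedigree members."""
    if a not in pedigree.members:
        raise KeyError(f"individual {a!r} not in pedigree")
    if b not in pedigree.members:
        raise KeyError(f"individual {b!r} not in pedigree")
    depth = pedigree._topological_depths()
    cache: dict[frozenset[str] | str, Fraction] = {}

    def phi(i: str, j: str) -> Fraction:
        key = i if i == j else frozenset((i, j))
        if key in cache:
            return cache[key]
        fa_i, mo_i = pedigree.members[i]
        if i == j:
            inb = Fraction(0) if fa_i is None else phi(fa_i, mo_i)
            out = Fraction(1, 2) * (1 + inb)
        else:
            # Expand the individual furthest from the founders; this is safe
            # because that one cannot be an ancestor of the other.
            if depth[i] < depth[j]:
                i, j = j, i
                fa_i, mo_i = pedigree.members[i]
            if fa_i is None:  # both founders, distinct
                out = Fraction(0)
            else:
                out = Fraction(1, 2) * (phi(fa_i, j) + phi(mo_i, j))
        cache[key] = out
        return out

    return phi(a, b)


def expected_inbreeding(pedigree: PedigreeSpec, individual: str) -> Fraction:
    """Inbreeding coefficient F of ``individual`` = kinship of its parents.

    F is also the expected autozygous fraction of the autosomal genome, the
    quantity the realized runs-of-homozygosity total is compared against.
    """
    fa, mo = pedigree.parents(individual)
    if fa is None:
        return Fraction(0)
    return kinship(pedigree, fa, mo)
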