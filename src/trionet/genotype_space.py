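"""The 21-genotype space over six allele classes and the Mendelian trio predicate.

Diploid genotypes are modelled as unordered pairs over the allele alphabet
{A, C, G, T, Ins, Del}: 21 classes in total.  Ins/Del are opaque classes with
no length semantics at this layer.  A trio genotype (child, parent1, parent2)
is Mendelian-consistent when the child's two alleles can be drawn one from
each parent; otherwise one or two child alleles are unexplained, and the
"valid degree" beta of the triple is (1-mu)^2, mu or mu^2 respectively, with
mu the per-generation mutation rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable

import numpy as np

__all__ = [
    "Allele",
    "Genotype21",
    "TrioGenotype",
    "BetaTable",
    "N_GENOTYPES",
    "GENOTYPE_PAIRS",
    "encode_genotype",
    "decode_genotype",
    "mismatch_count",
    "mismatch_table",
    "is_mendelian_consistent",
    "build_beta_table",
    "genotype_from_vcf_gt",
    "allele_class_of_vcf_allele",
]


class InvalidAlleleError(ValueError):
    """Raised for a symbol outside the six allele classes."""


class Allele(enum.IntEnum):
    """Six allele classes, totally ordered A < C < G < T < Ins < Del."""

    A = 0
    C = 1
    G = 2
    T = 3
    Ins = 4
    Del = 5

    @classmethod
    def from_symbol(cls, symbol: "Allele | str | int") -> "Allele":
        if isinstance(symbol, Allele):
            return symbol
        if isinstance(symbol, str):
            key = symbol.capitalize() if symbol.lower() in ("ins", "del") else symbol.upper()
            try:
                return cls[key]
            except KeyError:
                raise InvalidAlleleError(f"not an allele class: {symbol!r}") from None
        try:
            return cls(int(symbol))
        except ValueError:
            raise InvalidAlleleError(f"not an allele class: {symbol!r}") from None


N_ALLELES = 6
N_GENOTYPES = 21

#: canonical listing of the 21 unordered pairs: (A,A), (A,C), ..., (Del,Del)
GENOTYPE_PAIRS: tuple[tuple[Allele, Allele], ...] = tuple(
    (Allele(a), Allele(b)) for a, b in combinations_with_replacement(range(N_ALLELES), 2)
)

_PAIR_TO_INDEX = {pair: i for i, pair in enumerate(GENOTYPE_PAIRS)}


@dataclass(frozen=True, order=True)
class Genotype21:
    """One of the 21 unordered diploid genotype classes."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_GENOTYPES:
            raise ValueError(f"genotype index out of range: {self.index}")

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return GENOTYPE_PAIRS[self.index]

    def is_homozygous(self) -> bool:
        a, b = self.alleles
        return a == b

    def __str__(self) -> str:
        a, b = self.alleles
        return f"{a.name}/{b.name}"


def encode_genotype(allele_a: Allele | str | int, allele_b: Allele | str | int) -> Genotype21:
    """Return the canonical unordered-pair class; symmetric in its arguments."""
    a = Allele.from_symbol(allele_a)
    b = Allele.from_symbol(allele_b)
    if a > b:
        a, b = b, a
    return Genotype21(_PAIR_TO_INDEX[(a, b)])


def decode_genotype(genotype: Genotype21 | int) -> tuple[Allele, Allele]:
    """Inverse of :func:`encode_genotype` up to allele order."""
    index = genotype.index if isinstance(genotype, Genotype21) else int(genotype)
    return GENOTYPE_PAIRS[index]


@dataclass(frozen=True)
class TrioGenotype:
    """Ordered triple (child, parent1, parent2) of genotype classes."""

    child: Genotype21
    parent1: Genotype21
    parent2: Genotype21

    def mismatch_count(self) -> int:
        return mismatch_count(self.child, self.parent1, self.parent2)

    def is_mendelian_consistent(self) -> bool:
        return self.mismatch_count() == 0


def _as_index(g: Genotype21 | int) -> int:
    return g.index if isinstance(g, Genotype21) else int(g)


def mismatch_count(child: Genotype21 | int, p1: Genotype21 | int, p2: Genotype21 | int) -> int:
    """Number of child alleles (0, 1 or 2) that cannot be inherited.

    The child's two alleles are assigned one to each parent; over the two
    possible assignments the minimum number of alleles absent from the
    assigned parent's genotype is returned.  Unphased genotypes make the
    assignment ambiguous, so the most permissive (minimum) reading is used.
    Symmetric under swapping the parents.
    """
    return int(MISMATCH_TABLE[_as_index(child), _as_index(p1), _as_index(p2)])


def _mismatch_scalar(child: int, p1: int, p2: int) -> int:
    ca, cb = GENOTYPE_PAIRS[child]
    pa = GENOTYPE_PAIRS[p1]
    pb = GENOTYPE_PAIRS[p2]
    direct = (ca not in pa) + (cb not in pb)
    swapped = (cb not in pa) + (ca not in pb)
    return min(direct, swapped)


def _build_mismatch_table() -> np.ndarray:
    table = np.empty((N_GENOTYPES, N_GENOTYPES, N_GENOTYPES), dtype=np.uint8)
    for c in range(N_GENOTYPES):
        for i in range(N_GENOTYPES):
            for j in range(N_GENOTYPES):
                table[c, i, j] = _mismatch_scalar(c, i, j)
    return table


#: mismatch_count over all 21^3 triples, indexed [child, parent1, parent2]
MISMATCH_TABLE: np.ndarray = _build_mismatch_table()
MISMATCH_TABLE.setflags(write=False)


def mismatch_table() -> np.ndarray:
    """Read-only (21, 21, 21) uint8 array of mismatch counts."""
    return MISMATCH_TABLE


def is_mendelian_consistent(
    child: Genotype21 | int, p1: Genotype21 | int, p2: Genotype21 | int
) -> bool:
    """True iff the child genotype can be assembled from one allele per parent."""
    return mismatch_count(child, p1, p2) == 0


@dataclass(frozen=True)
class BetaTable:
    """Valid-degree prior over all 9261 trio genotype triples.

    ``values[c, i, j]`` is (1-mu)^2 for a Mendelian-consistent triple, mu for
    one child-allele mismatch and mu^2 for two, with mu the per-generation
    mutation rate.
    """

    mu: float
    values: np.ndarray  # (21, 21, 21) float64, indexed [child, p1, p2]

    @property
    def branch_values(self) -> tuple[float, float, float]:
        """(beta at 0 mismatches, at 1, at 2)."""
        return ((1.0 - self.mu) ** 2, self.mu, self.mu**2)

    def value(self, child: Genotype21 | int, p1: Genotype21 | int, p2: Genotype21 | int) -> float:
        return float(self.values[_as_index(child), _as_index(p1), _as_index(p2)])

    def to_rows(self) -> Iterable[tuple[int, int, int, int, float]]:
        """Debug serialization: (index_c, index_p1, index_p2, mismatch, beta)."""
        for c in range(N_GENOTYPES):
            for i in range(N_GENOTYPES):
                for j in range(N_GENOTYPES):
                    yield (c, i, j, int(MISMATCH_TABLE[c, i, j]), float(self.values[c, i, j]))


def build_beta_table(mu: float = 1e-8) -> BetaTable:
    """Build the valid-degree table for mutation rate ``mu`` in (0, 1)."""
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mutation rate must lie in (0, 1), got {mu}")
    branch = np.array([(1.0 - mu) ** 2, mu, mu**2])
    values = branch[MISMATCH_TABLE]
    values.setflags(write=False)
    return BetaTable(mu=mu, values=values)


# --- bridge from VCF records to the 21-class space ---------------------------

_BASES = {"A": Allele.A, "C": Allele.C, "G": Allele.G, "T": Allele.T}


def allele_class_of_vcf_allele(allele: str, ref: str) -> Allele:
    """Collapse a VCF allele string onto an allele class.

    Length-1 base strings map to their base class when the REF is also length
    1; longer-than-REF alleles are insertions, shorter ones deletions.  The
    REF allele maps to the class of its first base.  Symbolic ``<DEL>``/
    ``<INS>`` alleles are honoured.
    """
    allele = allele.upper()
    ref = ref.upper()
    if allele in ("<DEL>", "*"):
        return Allele.Del
    if allele == "<INS>":
        return Allele.Ins
    if allele == ref:
        return _BASES.get(ref[0], Allele.A)
    if len(allele) > len(ref):
        return Allele.Ins
    if len(allele) < len(ref):
        return Allele.Del
    if len(allele) == 1 and allele in _BASES:
        return _BASES[allele]
    # equal-length multi-base substitution: class of the first differing base
    for r, a in zip(ref, allele):
        if r != a and a in _BASES:
            return _BASES[a]
    raise InvalidAlleleError(f"cannot classify VCF allele {allele!r} against REF {ref!r}")


def genotype_from_vcf_gt(
    gt: tuple[int | None, int | None], ref: str, alts: tuple[str, ...]
) -> Genotype21 | None:
    """Map a VCF GT index pair onto Genotype21 via the site's REF/ALT alleles.

    Returns None for missing or half-called genotypes.  Multiallelic records
    beyond two ALTs use only the first two (extra ALT indices are treated as
    missing).
    """
    if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
        return None
    site_alleles = (ref,) + tuple(alts[:2] if alts else ())
    try:
        a = site_alleles[gt[0]]
        b = site_alleles[gt[1]]
    except IndexError:
        return None
    return encode_genotype(
        allele_class_of_vcf_allele(a, ref), allele_class_of_vcf_allele(b, ref)
    )
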