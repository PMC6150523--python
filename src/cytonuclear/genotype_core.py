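"""Domain types and elementary genetic operations.

A genotype is written as a five-character string ``[af][AF][AF][Mm][Mm]``,
e.g. ``aAFMm``: the mitochondrial COI haplotype first, then the ordered 28S
diplotype, then the ordered M-locus diplotype.  Within each nuclear pair the
first allele is of maternal origin, so ``Mm`` and ``mM`` are distinct
genotypes (same phenotype) and ``aAF`` denotes a hybrid from an *E. andrei*
ovum while ``fFA`` denotes the reciprocal hybrid from an *E. fetida* ovum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

MITO_HAPLOTYPES = ("a", "f")
SPECIES_ALLELES = ("A", "F")
M_ALLELES = ("M", "m")

MStatus = Literal["Mp", "Mn"]
ClassLabel = Literal["Ea", "Ef", "hybrid_Ea_derived", "hybrid_Ef_derived"]


@dataclass(frozen=True, order=True)
class Genotype:
    """Cytonuclear genotype: mito haplotype + two ordered nuclear diplotypes.

    Both nuclear pairs are maternal-first; parent of origin is retained, so
    ``Genotype.from_string("aAAMm") != Genotype.from_string("aAAmM")`` even
    though the two have identical phenotypes.  Use :meth:`unordered_key` for
    tabulations that should pool such pairs.
    """

    mito: str
    species: tuple[str, str]
    m: tuple[str, str]

    def __post_init__(self) -> None:
        if self.mito not in MITO_HAPLOTYPES:
            raise ValueError(f"invalid mito haplotype {self.mito!r} (position 1): expected one of {MITO_HAPLOTYPES}")
        for i, allele in enumerate(self.species):
            if allele not in SPECIES_ALLELES:
                raise ValueError(f"invalid 28S allele {allele!r} (position {2 + i}): expected one of {SPECIES_ALLELES}")
        for i, allele in enumerate(self.m):
            if allele not in M_ALLELES:
                raise ValueError(f"invalid M-locus allele {allele!r} (position {4 + i}): expected one of {M_ALLELES}")

    @classmethod
    def from_string(cls, code: str) -> "Genotype":
        """Parse a five-character genotype code such as ``aAFMm``."""
        if len(code) != 5:
            raise ValueError(f"genotype code must have 5 characters, got {code!r}")
        return cls(mito=code[0], species=(code[1], code[2]), m=(code[3], code[4]))

    def __str__(self) -> str:
        return self.mito + "".join(self.species) + "".join(self.m)

    def unordered_key(self) -> tuple[str, frozenset[tuple[str, int]], frozenset[tuple[str, int]]]:
        """Equivalence key ignoring parental origin within each nuclear pair."""

        def counted(pair: tuple[str, str]) -> frozenset[tuple[str, int]]:
            return frozenset((a, pair.count(a)) for a in set(pair))

        return (self.mito, counted(self.species), counted(self.m))

    @property
    def is_hybrid(self) -> bool:
        """True when the 28S diplotype is heterozygous (AF or FA)."""
        return self.species[0] != self.species[1]

    @property
    def is_ef_derived_hybrid(self) -> bool:
        """True for fFA-type hybrids (f mito, heterozygous 28S)."""
        return self.mito == "f" and self.is_hybrid


@dataclass(frozen=True)
class Gamete:
    """Ovum or sperm carrying one allele per nuclear locus.

    Ova carry the parent's mitochondrial haplotype; sperm never do.
    """

    kind: Literal["ovum", "sperm"]
    species_allele: str
    m_allele: str
    mito: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ovum", "sperm"):
            raise ValueError(f"gamete kind must be 'ovum' or 'sperm', got {self.kind!r}")
        if self.kind == "ovum" and self.mito not in MITO_HAPLOTYPES:
            raise ValueError("ova must carry a mitochondrial haplotype")
        if self.kind == "sperm" and self.mito is not None:
            raise ValueError("sperm must not carry a mitochondrial haplotype")
        if self.species_allele not in SPECIES_ALLELES:
            raise ValueError(f"invalid 28S allele {self.species_allele!r}")
        if self.m_allele not in M_ALLELES:
            raise ValueError(f"invalid M-locus allele {self.m_allele!r}")

    def __str__(self) -> str:
        prefix = self.mito if self.kind == "ovum" else ""
        return f"{prefix}{self.species_allele}{self.m_allele}"


@dataclass(frozen=True)
class Phenotype:
    """Observable state: fluorophore status and reporting class.

    ``m_status`` is Mp iff the M-locus carries at least one dominant M
    allele.  ``class_label`` combines the maternal lineage (mito) with the
    28S composition: aAA -> Ea, fFF -> Ef, heterozygotes -> hybrid of the
    corresponding maternal derivation.
    """

    m_status: MStatus
    class_label: ClassLabel


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the mating/inheritance model.

    selfing_rate
        Per-ovum probability that an ovum is self-fertilized rather than
        cross-fertilized by the partner (hermaphrodites do both).
    ef_cross_success
        Weight on cross-fertilization of f-mito ova by A-bearing sperm; the
        asymmetry knob. 0 forbids fFA hybrids entirely.
    af_ovum_viability
        Viability of ova combining an 'a' mitochondrion with a nuclear 'F'
        allele (mito-nuclear incompatibility). 0 = hard exclusion.
    hybrid_selfing_enabled
        Whether heterozygous-28S mothers contribute self-fertilized
        offspring.
    symbiont_vertical_p
        Probability that an infected mother transmits the symbiont through
        the cocoon to an offspring.
    symbiont_sexual_p
        Probability that an infected father infects the uninfected mother's
        cocoon during copulation (resolved once per pairing).
    """

    selfing_rate: float = 0.5
    ef_cross_success: float = 0.1
    af_ovum_viability: float = 0.0
    hybrid_selfing_enabled: bool = False
    symbiont_vertical_p: float = 1.0
    symbiont_sexual_p: float = 0.5
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "selfing_rate",
            "ef_cross_success",
            "af_ovum_viability",
            "symbiont_vertical_p",
            "symbiont_sexual_p",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def make_gametes(g: Genotype, kind: Literal["ovum", "sperm"]) -> dict[Gamete, float]:
    """Exact gamete distribution of a genotype.

    The two nuclear loci segregate independently, each transmitting either
    allele with probability 1/2.  Ova carry ``g.mito``; sperm carry no
    mitochondria.  The support has size 1, 2 or 4 depending on heterozygosity.
    """
    dist: dict[Gamete, float] = {}
    mito = g.mito if kind == "ovum" else None
    for species_allele in g.species:
        for m_allele in g.m:
            gam = Gamete(kind=kind, species_allele=species_allele, m_allele=m_allele, mito=mito)
            dist[gam] = dist.get(gam, 0.0) + 0.25
    return dist


def fertilize(ovum: Gamete, sperm: Gamete) -> Genotype:
    """Fuse an ovum and a sperm into a zygote genotype.

    The zygote inherits the ovum's mitochondrion; each nuclear pair is
    (ovum allele, sperm allele), i.e. maternal-first.
    """
    if ovum.kind != "ovum" or sperm.kind != "sperm":
        raise ValueError(f"fertilize requires (ovum, sperm), got ({ovum.kind}, {sperm.kind})")
    assert ovum.mito is not None
    return Genotype(
        mito=ovum.mito,
        species=(ovum.species_allele, sperm.species_allele),
        m=(ovum.m_allele, sperm.m_allele),
    )


def ovum_viability(ovum: Gamete, params: ModelParams) -> float:
    """Viability weight of an ovum under mito-nuclear incompatibility.

    Ova pairing an 'a' mitochondrion with a nuclear 'F' allele are viable
    with probability ``params.af_ovum_viability`` (default 0, reproducing
    hard exclusion of aF ova); all other ova have weight 1.
    """
    if ovum.kind != "ovum":
        raise ValueError("ovum_viability requires an ovum")
    if ovum.mito == "a" and ovum.species_allele == "F":
        return params.af_ovum_viability
    return 1.0


def is_fertile_mother(g: Genotype, params: ModelParams | None = None) -> bool:
    """Whether a genotype can mother offspring at all.

    fFA hybrids are maternally sterile (their ova yield no hatchlings).
    """
    return not g.is_ef_derived_hybrid


def is_fertile_father(g: Genotype, params: ModelParams | None = None) -> bool:
    """Whether a genotype can sire offspring as sperm donor.

    fFA hybrids are treated as fully sterile by default; no successful fFA
    parent of either role has been observed.
    """
    return not g.is_ef_derived_hybrid


def is_fertile_pairing(g1: Genotype, g2: Genotype) -> bool:
    """Whether a pair of hermaphrodites can produce any offspring.

    Hybrid x hybrid pairings are infertile (plenty of cocoons, no
    hatchlings), and fFA individuals are sterile in either parental role;
    a pairing is fertile when at least one partner is a fertile mother and
    the pairing is not hybrid x hybrid.
    """
    if g1.is_hybrid and g2.is_hybrid:
        return False
    return is_fertile_mother(g1) or is_fertile_mother(g2)


def phenotype(g: Genotype) -> Phenotype:
    """Map a genotype to its phenotype (total, deterministic).

    M-positivity is dominant: Mp iff at least one 'M' allele.  The class
    label is a pure function of the mito haplotype and the unordered 28S
    composition.
    """
    m_status: MStatus = "Mp" if "M" in g.m else "Mn"
    if g.is_hybrid:
        label: ClassLabel = "hybrid_Ea_derived" if g.mito == "a" else "hybrid_Ef_derived"
    else:
        label = "Ea" if g.mito == "a" else "Ef"
    return Phenotype(m_status=m_status, class_label=label)


def classify_specimen(coi: str, species_diplotype: tuple[str, str] | str, m_status: str) -> tuple[ClassLabel, str]:
    """Classify an observed specimen from its markers.

    Parameters are the raw observed fields: COI haplotype ('a'/'f'), the
    ordered 28S diplotype (string like 'FA' or a 2-tuple) and the observed
    M status ('Mp'/'Mn'/'unknown').  Returns (class_label, m_status)
    unchanged in status, validated with position information on error.
    """
    if coi not in MITO_HAPLOTYPES:
        raise ValueError(f"invalid COI haplotype {coi!r} (position 1): expected one of {MITO_HAPLOTYPES}")
    pair = tuple(species_diplotype)
    if len(pair) != 2:
        raise ValueError(f"28S diplotype must have two alleles, got {species_diplotype!r}")
    for i, allele in enumerate(pair):
        if allele not in SPECIES_ALLELES:
            raise ValueError(f"invalid 28S allele {allele!r} (position {2 + i}): expected one of {SPECIES_ALLELES}")
    if m_status not in ("Mp", "Mn", "unknown"):
        raise ValueError(f"invalid M status {m_status!r}: expected Mp, Mn or unknown")
    if pair[0] != pair[1]:
        label: ClassLabel = "hybrid_Ea_derived" if coi == "a" else "hybrid_Ef_derived"
    else:
        label = "Ea" if coi == "a" else "Ef"
    return label, m_status
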