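"""Classification, pedigree genotype inference, and likelihood machinery.

Covers four layers of analysis: (1) mapping observed markers to the study's
reporting classes and tabulating class x M-status counts; (2) constraint
propagation of compatible M-locus diplotypes through a pedigree; (3)
maximum-likelihood estimation of the selfing rate and the asymmetric
hybridization weight from class counts; (4) likelihood comparison of the
Mendelian (dominant M allele) and symbiont-infection mechanisms on family
phenotype counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from cytonuclear.genotype_core import Genotype, ModelParams, classify_specimen, phenotype
from cytonuclear.pedigree_sim import MatingDesign, SpecimenRecord
from cytonuclear.punnett import (
    OffspringDistribution,
    class_distribution,
    pair_distribution,
    self_distribution,
)

CLASS_KEYS = [
    ("Ea", "Mp"),
    ("Ea", "Mn"),
    ("hybrid_Ea_derived", "Mp"),
    ("hybrid_Ea_derived", "Mn"),
    ("Ef", "Mp"),
    ("Ef", "Mn"),
    ("hybrid_Ef_derived", "Mp"),
    ("hybrid_Ef_derived", "Mn"),
]

M_DIPLOTYPES = ("MM", "Mm", "mM", "mm")


@dataclass(frozen=True)
class ClassCount:
    """Counts per (class_label, m_status); ``total`` is their sum."""

    counts: dict[tuple[str, str], int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("class counts do not sum to total")

    def get(self, class_label: str, m_status: str) -> int:
        return self.counts.get((class_label, m_status), 0)


def tabulate(records: list[SpecimenRecord]) -> ClassCount:
    """Exact class x M-status counts of a specimen table."""
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.coi is None or rec.species_diplotype is None:
            raise ValueError(f"specimen {rec.id} lacks markers required for classification")
        label, status = classify_specimen(rec.coi, rec.species_diplotype, rec.m_status)
        key = (label, status)
        counts[key] = counts.get(key, 0) + 1
    return ClassCount(counts=counts, total=len(records))


# ---------------------------------------------------------------------------
# M-locus genotype inference through pedigrees (arc-consistency fixpoint)


@dataclass(frozen=True)
class MGenotypeSet:
    """Compatible ordered M-locus diplotypes of one specimen."""

    specimen_id: str
    diplotypes: frozenset[str]


@dataclass
class InferenceResult:
    sets: dict[str, frozenset[str]]
    inconsistencies: list[tuple[str, str]] = field(default_factory=list)

    def as_list(self) -> list[MGenotypeSet]:
        return [MGenotypeSet(sid, dip) for sid, dip in sorted(self.sets.items())]


def _initial_domain(m_status: str) -> set[str]:
    if m_status == "Mn":
        return {"mm"}
    if m_status == "Mp":
        return {"MM", "Mm", "mM"}
    return set(M_DIPLOTYPES)


def infer_m_genotypes(records: list[SpecimenRecord]) -> InferenceResult:
    """Compatible M-locus diplotype sets jointly consistent with a pedigree.

    Starts from the phenotype constraint (Mp excludes mm; Mn forces mm) and
    iterates two prunings until no set shrinks: a child diplotype must be
    transmissible from its parents' surviving sets, and a parent diplotype
    must be able to supply the required allele to every child.  A specimen
    whose set empties is reported as an inconsistency (with the violated
    constraint) rather than raising.
    """
    by_id = {r.id: r for r in records}
    domains: dict[str, set[str]] = {r.id: _initial_domain(r.m_status) for r in records}
    children_of: dict[str, list[tuple[str, str]]] = {}  # parent -> [(child, role)]
    for r in records:
        for role, pid in (("mother", r.mother_id), ("father", r.father_id)):
            if pid is not None and pid in by_id:
                children_of.setdefault(pid, []).append((r.id, role))

    inconsistencies: list[tuple[str, str]] = []

    def transmissible(domain: set[str]) -> set[str]:
        return {allele for dip in domain for allele in dip}

    changed = True
    while changed:
        changed = False
        for r in records:
            dom = domains[r.id]
            if not dom:
                continue
            # child-side: each ordered diplotype needs a maternal and a paternal source
            for role, pid, pos in (("mother", r.mother_id, 0), ("father", r.father_id, 1)):
                if pid is None or pid not in domains or not domains[pid]:
                    continue
                alleles = transmissible(domains[pid])
                keep = {d for d in dom if d[pos] in alleles}
                if keep != dom:
                    domains[r.id] = dom = keep
                    changed = True
                    if not dom:
                        inconsistencies.append(
                            (r.id, f"{role} {pid} cannot transmit the required {'maternal' if pos == 0 else 'paternal'} allele")
                        )
        # parent-side: a parent diplotype must serve every child
        for pid, kids in children_of.items():
            dom = domains[pid]
            if not dom:
                continue
            keep = set(dom)
            for child_id, role in kids:
                child_dom = domains[child_id]
                if not child_dom:
                    continue
                pos = 0 if role == "mother" else 1
                needed = {d[pos] for d in child_dom}
                keep = {dip for dip in keep if set(dip) & needed}
            if keep != dom:
                domains[pid] = keep
                changed = True
                if not keep:
                    inconsistencies.append((pid, "no diplotype can supply alleles required by all offspring"))
    return InferenceResult(sets={sid: frozenset(dom) for sid, dom in domains.items()}, inconsistencies=inconsistencies)


# ---------------------------------------------------------------------------
# (sigma, h) estimation from class counts


def design_class_probs(design: MatingDesign, params: ModelParams) -> dict[tuple[str, str], float]:
    """Exact class probabilities of a random specimen from a design's offspring.

    Crosses are mixed in proportion to their offspring counts.  Selectors
    referencing an offspring class (e.g. the Ea-derived hybrid picked from
    the F1) are resolved to the conditional genotype distribution of that
    class among earlier crosses, so the result is the exact expectation of
    the simulated class composition.
    """
    produced: dict[Genotype, float] = {}

    def resolve(selector: str) -> dict[Genotype, float]:
        if selector.startswith("class:"):
            label = selector[len("class:") :].partition("@")[0]
            cond = {g: w for g, w in produced.items() if phenotype(g).class_label == label}
            total = sum(cond.values())
            if total == 0:
                raise ValueError(f"selector {selector!r}: class not produced by earlier crosses")
            return {g: w / total for g, w in cond.items()}
        return {Genotype.from_string(selector): 1.0}

    per_class: dict[tuple[str, str], float] = {}
    total_n = sum(c.n_offspring for c in design.crosses)
    for cross in design.crosses:
        mothers = resolve(cross.mother)
        fathers = resolve(cross.father)
        mix: dict[Genotype, float] = {}
        for gm, wm in mothers.items():
            for gf, wf in fathers.items():
                d = pair_distribution(gm, gf, params)
                for g, p in d.entries.items():
                    mix[g] = mix.get(g, 0.0) + wm * wf * p
        z = sum(mix.values())
        if z > 0:
            for g, p in mix.items():
                produced[g] = produced.get(g, 0.0) + cross.n_offspring * p / z
                key_ph = phenotype(g)
                key = (key_ph.class_label, key_ph.m_status)
                per_class[key] = per_class.get(key, 0.0) + (cross.n_offspring / total_n) * p / z
    return per_class


@dataclass
class FitResult:
    """Grid-search ML fit of (selfing rate, Ef-cross success)."""

    sigma_hat: float
    h_hat: float
    sigma_grid: np.ndarray
    h_grid: np.ndarray
    loglik: np.ndarray  # shape (len(sigma_grid), len(h_grid))
    flat: bool
    impossible_classes: list[tuple[str, str]]


def grid_class_probs(
    design: MatingDesign,
    sigma_grid: np.ndarray,
    h_grid: np.ndarray,
    base_params: ModelParams | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Class-probability surfaces over a (sigma, h) grid, reusable across fits."""
    from dataclasses import replace

    base = base_params or ModelParams()
    surfaces: dict[tuple[str, str], np.ndarray] = {
        key: np.zeros((len(sigma_grid), len(h_grid))) for key in CLASS_KEYS
    }
    for i, sigma in enumerate(sigma_grid):
        for j, h in enumerate(h_grid):
            probs = design_class_probs(design, replace(base, selfing_rate=float(sigma), ef_cross_success=float(h)))
            for key, p in probs.items():
                surfaces[key][i, j] = p
    return surfaces


def estimate_params(
    counts: ClassCount,
    design: MatingDesign,
    grid_points: int = 101,
    base_params: ModelParams | None = None,
    surfaces: dict[tuple[str, str], np.ndarray] | None = None,
    sigma_grid: np.ndarray | None = None,
    h_grid: np.ndarray | None = None,
) -> FitResult:
    """Maximize the multinomial log-likelihood of class counts on a grid.

    A plain grid search (default 101 x 101 over the unit square) is used
    deliberately: the surface can be flat or maximized on a boundary, and
    the full surface is returned for inspection.  Ties break toward the
    smallest (sigma, h) in row-major order.  Observed classes with zero
    probability everywhere on the grid are reported in
    ``impossible_classes`` (the likelihood is -inf on the whole grid).
    """
    if sigma_grid is None:
        sigma_grid = np.linspace(0.0, 1.0, grid_points)
    if h_grid is None:
        h_grid = np.linspace(0.0, 1.0, grid_points)
    if surfaces is None:
        surfaces = grid_class_probs(design, sigma_grid, h_grid, base_params)
    loglik = np.zeros((len(sigma_grid), len(h_grid)))
    observed = [(key, n) for key, n in counts.counts.items() if n > 0]
    impossible = []
    with np.errstate(divide="ignore"):
        for key, n in observed:
            p = surfaces.get(key)
            if p is None or not np.any(p > 0):
                impossible.append(key)
                loglik[:] = -np.inf
                continue
            loglik = loglik + n * np.log(p)
    finite = loglik[np.isfinite(loglik)]
    flat = finite.size == 0 or bool(np.ptp(finite) < 1e-9)
    best = np.unravel_index(int(np.argmax(loglik)), loglik.shape)
    return FitResult(
        sigma_hat=float(sigma_grid[best[0]]),
        h_hat=float(h_grid[best[1]]),
        sigma_grid=sigma_grid,
        h_grid=h_grid,
        loglik=loglik,
        flat=flat,
        impossible_classes=impossible,
    )


# ---------------------------------------------------------------------------
# Mendelian vs symbiont mechanism comparison on family phenotype counts


@dataclass(frozen=True)
class Family:
    """One brood: parent description plus offspring Mp/Mn counts.

    ``father_genotype`` None means a purely self-fertilizing mother.
    Infection flags matter only under the symbiont mechanism.
    """

    mother_genotype: Genotype
    father_genotype: Genotype | None
    n_offspring: int
    n_mn: int
    mother_infected: bool = True
    father_infected: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_mn <= self.n_offspring:
            raise ValueError("need 0 <= n_mn <= n_offspring")


def _mendelian_p_mn(family: Family, params: ModelParams) -> float:
    if family.father_genotype is None:
        d = self_distribution(family.mother_genotype, params)
    else:
        d = pair_distribution(family.mother_genotype, family.father_genotype, params)
    if d.is_empty:
        return float("nan")
    return sum(p for (_, status), p in class_distribution(d).items() if status == "Mn")


def mechanism_loglik(family: Family, mechanism: str, params: ModelParams | None = None) -> float:
    """Log-likelihood of a family's Mn count under one inheritance mechanism.

    mendelian
        Binomial with P(Mn) taken from the exact offspring distribution of
        the family's mating configuration.
    symbiont
        Offspring are Mp iff infected.  An infected mother's cocoon is
        infected; an uninfected mother's cocoon becomes infected with
        probability ``symbiont_sexual_p`` when the father is infected.  An
        infected cocoon yields Mn offspring with probability
        ``1 - symbiont_vertical_p`` each; an uninfected cocoon yields all-Mn.
    Zero-probability observations return -inf.
    """
    params = params or ModelParams()
    n, k = family.n_offspring, family.n_mn
    if mechanism == "mendelian":
        p_mn = _mendelian_p_mn(family, params)
        if np.isnan(p_mn):
            return float("-inf")
        return float(binom.logpmf(k, n, p_mn))
    if mechanism == "symbiont":
        if family.mother_infected:
            p_cocoon = 1.0
        elif family.father_infected:
            p_cocoon = params.symbiont_sexual_p
        else:
            p_cocoon = 0.0
        lik = p_cocoon * float(binom.pmf(k, n, 1.0 - params.symbiont_vertical_p))
        lik += (1.0 - p_cocoon) * (1.0 if k == n else 0.0)
        with np.errstate(divide="ignore"):
            return float(np.log(lik))
    raise ValueError(f"unknown mechanism {mechanism!r}")


def mechanism_comparison(family: Family, params: ModelParams | None = None) -> dict[str, float]:
    """Log-likelihoods of both mechanisms and their log ratio (mendelian - symbiont)."""
    ll_m = mechanism_loglik(family, "mendelian", params)
    ll_s = mechanism_loglik(family, "symbiont", params)
    return {"mendelian": ll_m, "symbiont": ll_s, "log_ratio": ll_m - ll_s}
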