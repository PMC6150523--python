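"""Exact offspring-genotype distributions (Punnett enumeration).

A mating configuration is resolved per ovum: each ovum of the mother is
self-fertilized with probability ``selfing_rate`` and cross-fertilized by
partner sperm otherwise.  Event weights are multiplied by ovum viability
(mito-nuclear incompatibility of aF ova) and, for cross-fertilization of
f-mito ova by A-bearing sperm, by the asymmetric-hybridization weight
``ef_cross_success``.  Weights shift brood composition, not brood size: the
surviving mass is renormalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cytonuclear.genotype_core import (
    Genotype,
    ModelParams,
    fertilize,
    is_fertile_father,
    is_fertile_mother,
    is_fertile_pairing,
    make_gametes,
    ovum_viability,
    phenotype,
)



@dataclass(frozen=True)
class OffspringDistribution:
    """Probability map over viable offspring genotypes of one mating.

    ``normalization`` is the total event mass before renormalization; it is
    diagnostic (e.g. 0.55 when half the cross events were down-weighted).
    An empty support carries a ``reason`` code instead of probabilities.
    """

    entries: dict[Genotype, float] = field(default_factory=dict)
    normalization: float = 0.0
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(self.entries.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"nonempty distribution must sum to 1, got {total}")

    @property
    def is_empty(self) -> bool:
        return not self.entries

    def probability(self, g: Genotype | str) -> float:
        if isinstance(g, str):
            g = Genotype.from_string(g)
        return self.entries.get(g, 0.0)

    def support(self) -> set[Genotype]:
        return set(self.entries)

    def to_text(self) -> str:
        """Stable key/value rendering, one ``genotype<TAB>prob`` line per entry."""
        if self.is_empty:
            return f"# empty distribution: {self.reason}\n"
        lines = [f"{g}\t{p:.12g}" for g, p in sorted(self.entries.items(), key=lambda kv: str(kv[0]))]
        return "\n".join(lines) + "\n"


def _weighted_events(
    mother: Genotype,
    father: Genotype | None,
    params: ModelParams,
) -> dict[Genotype, float]:
    """Raw (unnormalized) offspring mass from one mother role.

    ``father=None`` means pure selfing.  Returns an empty dict when the
    mother is sterile or all events are weighted out.
    """
    if not is_fertile_mother(mother, params):
        return {}
    sigma = params.selfing_rate if father is not None else 1.0
    self_allowed = (not mother.is_hybrid) or params.hybrid_selfing_enabled
    events: dict[Genotype, float] = {}

    def add(ovum_dist, sperm_dist, weight, asym):
        for ovum, p_ov in ovum_dist.items():
            v = ovum_viability(ovum, params)
            if v == 0.0:
                continue
            for sperm, p_sp in sperm_dist.items():
                w = weight * p_ov * p_sp * v
                if asym and ovum.mito == "f" and sperm.species_allele == "A":
                    w *= params.ef_cross_success
                if w > 0.0:
                    child = fertilize(ovum, sperm)
                    events[child] = events.get(child, 0.0) + w

    ova = make_gametes(mother, "ovum")
    if self_allowed and sigma > 0.0:
        add(ova, make_gametes(mother, "sperm"), sigma, asym=False)
    if father is not None and (1.0 - sigma) > 0.0 and is_fertile_father(father, params):
        add(ova, make_gametes(father, "sperm"), 1.0 - sigma, asym=True)
    return events


def mating_components(
    g1: Genotype, g2: Genotype, params: ModelParams | None = None
) -> list[tuple[int, bool, Genotype, float]]:
    """Joint distribution over (mother role, selfed?, offspring genotype).

    Resolves a hermaphrodite pairing into its four fertilization routes
    (each partner's ova, self- or cross-fertilized) with the same weighting
    and per-role renormalization as :func:`pair_distribution`, which is its
    marginal over genotype.  Entries are ``(role_index, selfed, genotype,
    probability)`` with role_index 0 for ``g1``'s ova and 1 for ``g2``'s.
    """
    params = params or ModelParams()
    if not is_fertile_pairing(g1, g2):
        return []
    roles = []
    for idx, (gm, gf) in enumerate([(g1, g2), (g2, g1)]):
        if not is_fertile_mother(gm, params) or (gm.is_hybrid and gf.is_hybrid):
            continue
        sigma = params.selfing_rate
        self_allowed = (not gm.is_hybrid) or params.hybrid_selfing_enabled
        self_events: dict[Genotype, float] = {}
        cross_events: dict[Genotype, float] = {}
        ova = make_gametes(gm, "ovum")
        if self_allowed and sigma > 0.0:
            for ovum, p_ov in ova.items():
                v = ovum_viability(ovum, params)
                if v == 0.0:
                    continue
                for sperm, p_sp in make_gametes(gm, "sperm").items():
                    child = fertilize(ovum, sperm)
                    self_events[child] = self_events.get(child, 0.0) + sigma * p_ov * p_sp * v
        if (1.0 - sigma) > 0.0 and is_fertile_father(gf, params):
            for ovum, p_ov in ova.items():
                v = ovum_viability(ovum, params)
                if v == 0.0:
                    continue
                for sperm, p_sp in make_gametes(gf, "sperm").items():
                    w = (1.0 - sigma) * p_ov * p_sp * v
                    if ovum.mito == "f" and sperm.species_allele == "A":
                        w *= params.ef_cross_success
                    if w > 0.0:
                        child = fertilize(ovum, sperm)
                        cross_events[child] = cross_events.get(child, 0.0) + w
        total = sum(self_events.values()) + sum(cross_events.values())
        if total > 0.0:
            roles.append((idx, self_events, cross_events, total))
    out: list[tuple[int, bool, Genotype, float]] = []
    for idx, self_events, cross_events, total in roles:
        for selfed, events in ((True, self_events), (False, cross_events)):
            for g, w in events.items():
                out.append((idx, selfed, g, w / total / len(roles)))
    return out


def _finalize(events: dict[Genotype, float], reason: str) -> OffspringDistribution:
    total = sum(events.values())
    if total <= 0.0:
        return OffspringDistribution(entries={}, normalization=total, reason=reason)
    return OffspringDistribution(
        entries={g: w / total for g, w in events.items()},
        normalization=total,
    )


def self_distribution(g: Genotype, params: ModelParams | None = None) -> OffspringDistribution:
    """Offspring distribution of a purely self-fertilizing mother.

    Enumerates all own-ovum x own-sperm combinations, weighting ova by
    viability and renormalizing.  fFA mothers, and hybrid mothers unless
    ``hybrid_selfing_enabled``, yield an empty distribution with a reason
    code.
    """
    params = params or ModelParams()
    if not is_fertile_mother(g, params):
        return OffspringDistribution(reason="sterile_mother")
    if g.is_hybrid and not params.hybrid_selfing_enabled:
        return OffspringDistribution(reason="hybrid_selfing_disabled")
    events = _weighted_events(g, None, params)
    return _finalize(events, reason="no_viable_ova")


def cross_distribution(mother: Genotype, father: Genotype, params: ModelParams | None = None) -> OffspringDistribution:
    """Offspring distribution of one mother role within a pair.

    Each ovum selfs with probability ``selfing_rate`` and is crossed by
    partner sperm otherwise; asymmetry and viability weights apply, then the
    mass is renormalized.  Empty with a reason code when the mother is
    sterile or every event is excluded.
    """
    params = params or ModelParams()
    if not is_fertile_mother(mother, params):
        return OffspringDistribution(reason="sterile_mother")
    if mother.is_hybrid and father.is_hybrid:
        return OffspringDistribution(reason="hybrid_pairing_infertile")
    events = _weighted_events(mother, father, params)
    return _finalize(events, reason="all_events_excluded")


def pair_distribution(g1: Genotype, g2: Genotype, params: ModelParams | None = None) -> OffspringDistribution:
    """Offspring distribution of a hermaphrodite pair.

    Equal mixture of the two mother-role distributions; if one role is
    sterile or fully excluded the other carries all the mass.  Empty when
    the pairing is infertile (hybrid x hybrid, or no fertile mother).
    """
    params = params or ModelParams()
    if not is_fertile_pairing(g1, g2):
        return OffspringDistribution(reason="infertile_pairing")
    roles = [cross_distribution(g1, g2, params), cross_distribution(g2, g1, params)]
    live = [d for d in roles if not d.is_empty]
    if not live:
        return OffspringDistribution(reason="all_events_excluded")
    events: dict[Genotype, float] = {}
    for d in live:
        for g, p in d.entries.items():
            events[g] = events.get(g, 0.0) + p / len(live)
    return OffspringDistribution(entries=events, normalization=sum(d.normalization for d in live) / 2.0)


def class_distribution(d: OffspringDistribution) -> dict[tuple[str, str], float]:
    """Marginalize a genotype distribution to (class_label, m_status) mass.

    The pushforward through the phenotype map; sums to 1 for nonempty
    inputs and is empty for empty ones.
    """
    out: dict[tuple[str, str], float] = {}
    for g, p in d.entries.items():
        ph = phenotype(g)
        key = (ph.class_label, ph.m_status)
        out[key] = out.get(key, 0.0) + p
    return out
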