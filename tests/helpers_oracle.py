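"""Independent brute-force oracles used by the test suite.

These enumerate matings directly from allele lists with itertools, without
going through the package's gamete/fertilization code paths, so they can
serve as an independent check on the exact enumerator.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def oracle_offspring(
    mother: str,
    father: str | None,
    sigma: float = 0.5,
    h: float = 0.1,
    v: float = 0.0,
    hybrid_selfing: bool = False,
) -> dict[str, float]:
    """Brute-force offspring distribution of one mother role.

    ``mother``/``father`` are five-character genotype codes; ``father=None``
    means pure selfing.  Enumerates every (ovum, sperm-source, sperm)
    combination with its weight and renormalizes.  Returns {} for sterile
    configurations (fFA mother, hybrid x hybrid, hybrid selfing disabled
    when no partner exists).
    """

    def is_hybrid(code: str) -> bool:
        return code[1] != code[2]

    def is_ffa(code: str) -> bool:
        return code[0] == "f" and is_hybrid(code)

    if is_ffa(mother):
        return {}
    if father is not None and is_hybrid(mother) and is_hybrid(father):
        return {}

    weights: dict[str, float] = {}
    ova = [(mother[0], s, m, 0.25) for s in mother[1:3] for m in mother[3:5]]

    def sperm_of(code: str):
        return [(s, m, 0.25) for s in code[1:3] for m in code[3:5]]

    sources = []
    self_ok = (not is_hybrid(mother)) or hybrid_selfing
    if father is None:
        if self_ok:
            sources.append((1.0, sperm_of(mother), False))
    else:
        if self_ok:
            sources.append((sigma, sperm_of(mother), False))
        if not is_ffa(father):
            sources.append((1.0 - sigma, sperm_of(father), True))

    for mito, s_mat, m_mat, p_ov in ova:
        viability = v if (mito == "a" and s_mat == "F") else 1.0
        for src_w, sperm, is_cross in sources:
            for s_pat, m_pat, p_sp in sperm:
                w = src_w * p_ov * p_sp * viability
                if is_cross and mito == "f" and s_pat == "A":
                    w *= h
                if w > 0:
                    child = mito + s_mat + s_pat + m_mat + m_pat
                    weights[child] = weights.get(child, 0.0) + w
    total = sum(weights.values())
    if total <= 0:
        return {}
    return {g: w / total for g, w in weights.items()}


def oracle_pair(g1: str, g2: str, **kw) -> dict[str, float]:
    """Equal mixture of the two mother roles, skipping sterile roles."""
    roles = [oracle_offspring(g1, g2, **kw), oracle_offspring(g2, g1, **kw)]
    live = [r for r in roles if r]
    if not live:
        return {}
    out: dict[str, float] = {}
    for r in live:
        for g, p in r.items():
            out[g] = out.get(g, 0.0) + p / len(live)
    return out


def oracle_family_loglik(offspring_dist: dict[str, float], n: int, n_mn: int) -> float:
    """Log-probability of observing ``n_mn`` M-negative offspring out of ``n``.

    Brute force: sum the product probability over every ordered assignment
    of offspring genotypes whose Mn count equals ``n_mn``.  Exponential in
    ``n`` — use only for small families.
    """
    genotypes = sorted(offspring_dist)
    total = 0.0
    for combo in itertools.product(genotypes, repeat=n):
        mn = sum(1 for g in combo if "M" not in g[3:5])
        if mn == n_mn:
            p = 1.0
            for g in combo:
                p *= offspring_dist[g]
            total += p
    return math.log(total) if total > 0 else float("-inf")


def mn_mass(dist: dict[str, float]) -> float:
    return sum(p for g, p in dist.items() if "M" not in g[3:5])
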