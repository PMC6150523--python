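"""Seeded forward simulation of multi-generation mating designs.

Specimens are drawn independently from the exact pair distribution of their
parents, so the simulator and the Punnett enumerator agree by construction
up to sampling noise — a property the test suite checks.  The module also
implements the alternative, non-Mendelian mechanism: a maternally (and
occasionally sexually) transmitted symbiont whose presence, rather than a
nuclear genotype, determines M-positivity.

Specimen tables are plain tab-separated text with the fixed header
``id generation mother_id father_id coi nuc_mat nuc_pat m_mat m_pat
m_status infected weight_g``; missing values are empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from cytonuclear.genotype_core import Genotype, ModelParams, phenotype
from cytonuclear.punnett import mating_components

TABLE_COLUMNS = [
    "id",
    "generation",
    "mother_id",
    "father_id",
    "coi",
    "nuc_mat",
    "nuc_pat",
    "m_mat",
    "m_pat",
    "m_status",
    "infected",
    "weight_g",
]

#: default body-weight model (grams): normal truncated at zero
WEIGHT_MEAN_G = 0.77
WEIGHT_SD_G = 0.18


@dataclass(frozen=True)
class SpecimenRecord:
    """One simulated or observed earthworm.

    ``genotype`` is the hidden truth in simulation and may be absent for
    observed data; ``coi`` always equals the genotype's mito haplotype when
    the genotype is present.
    """

    id: str
    generation: int
    mother_id: str | None = None
    father_id: str | None = None
    genotype: Genotype | None = None
    coi: str | None = None
    species_diplotype: tuple[str, str] | None = None
    m_status: str = "unknown"
    symbiont_infected: bool | None = None
    body_weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.genotype is not None:
            if self.coi is None:
                object.__setattr__(self, "coi", self.genotype.mito)
            elif self.coi != self.genotype.mito:
                raise ValueError(f"specimen {self.id}: coi {self.coi!r} contradicts genotype {self.genotype}")
            if self.species_diplotype is None:
                object.__setattr__(self, "species_diplotype", self.genotype.species)


class CrossSpec(BaseModel):
    """One cross in a mating design.

    Selectors are either a five-character founder genotype code (a new
    founder is created), ``#some_id`` referencing an existing specimen, or
    ``class:<label>`` / ``class:<label>@<generation>`` picking the first
    matching specimen in id order.
    """

    mother: str
    father: str
    n_offspring: int = Field(ge=0)
    params: dict = Field(default_factory=dict)


class MatingDesign(BaseModel):
    """Ordered list of crosses executed generation after generation."""

    crosses: list[CrossSpec]
    founders_infected: dict[str, bool] = Field(default_factory=dict)


def study_design(n_f1: int = 30, n_f2: int = 30) -> MatingDesign:
    """The study's three-cross mating scheme.

    An Ea x Ef founder pair, then the resulting Ea-derived hybrid test-crossed
    back to each parental species.
    """
    return MatingDesign(
        crosses=[
            CrossSpec(mother="aAAMM", father="fFFmm", n_offspring=n_f1),
            CrossSpec(mother="class:hybrid_Ea_derived@1", father="aAAMM", n_offspring=n_f2),
            CrossSpec(mother="class:hybrid_Ea_derived@1", father="fFFmm", n_offspring=n_f2),
        ]
    )


def draw_weights(n: int, rng: np.random.Generator, mean: float = WEIGHT_MEAN_G, sd: float = WEIGHT_SD_G) -> np.ndarray:
    """Body weights from a normal(mean, sd) truncated at zero, by rejection."""
    if n == 0:
        return np.empty(0)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0.0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0.0
    return out


def transmit_symbiont(
    mother_infected: bool,
    father_infected: bool,
    params: ModelParams,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Symbiont status of ``n`` cocoon-mates of one pairing.

    If the mother is infected, each offspring is infected independently with
    probability ``symbiont_vertical_p``.  If only the father is infected, the
    cocoon itself becomes infected with probability ``symbiont_sexual_p``
    (one draw per pairing), after which the vertical rule applies.
    """
    cocoon_infected = bool(mother_infected)
    if not cocoon_infected and father_infected:
        cocoon_infected = bool(rng.random() < params.symbiont_sexual_p)
    if not cocoon_infected:
        return np.zeros(n, dtype=bool)
    return rng.random(n) < params.symbiont_vertical_p


def simulate_pair(
    mother: SpecimenRecord,
    father: SpecimenRecord,
    n: int,
    params: ModelParams,
    rng: np.random.Generator,
    generation: int | None = None,
    id_prefix: str = "0",
    weight_mean: float = WEIGHT_MEAN_G,
    weight_sd: float = WEIGHT_SD_G,
) -> list[SpecimenRecord]:
    """Draw ``n`` offspring of a pair; empty list when the pairing is infertile.

    Both partners are hermaphrodites, so pedigree links record the *genetic*
    roles per offspring: each partner mothers its own ova, and a
    self-fertilized offspring has father equal to its mother.  Symbiont
    transmission is resolved per genetic mother's cocoon.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("simulate_pair requires a seeded numpy Generator (reproducibility contract)")
    if mother.genotype is None or father.genotype is None:
        raise ValueError("simulated parents must carry genotypes")
    components = mating_components(mother.genotype, father.genotype, params)
    if not components or n == 0:
        return []
    generation = generation if generation is not None else max(mother.generation, father.generation) + 1
    components = sorted(components, key=lambda c: (c[0], c[1], str(c[2])))
    probs = np.array([c[3] for c in components])
    picks = rng.choice(len(components), size=n, p=probs / probs.sum())
    weights = draw_weights(n, rng, mean=weight_mean, sd=weight_sd)
    partners = (mother, father)
    # one cocoon-infection resolution per genetic mother
    infected_by_role = {
        idx: transmit_symbiont(
            bool(partners[idx].symbiont_infected),
            bool(partners[1 - idx].symbiont_infected),
            params,
            rng,
            n=n,
        )
        for idx in sorted({c[0] for c in components})
    }
    out = []
    for i in range(n):
        role, selfed, g, _ = components[int(picks[i])]
        genetic_mother = partners[role]
        genetic_father = genetic_mother if selfed else partners[1 - role]
        out.append(
            SpecimenRecord(
                id=f"{generation}_{id_prefix}_{i}",
                generation=generation,
                mother_id=genetic_mother.id,
                father_id=genetic_father.id,
                genotype=g,
                m_status=phenotype(g).m_status,
                symbiont_infected=bool(infected_by_role[role][i]),
                body_weight_g=float(weights[i]),
            )
        )
    return out


def _resolve_selector(
    selector: str,
    specimens: list[SpecimenRecord],
    founders: dict[str, SpecimenRecord],
    design: MatingDesign,
    next_gen: list[SpecimenRecord],
) -> SpecimenRecord:
    if selector.startswith("#"):
        wanted = selector[1:]
        for rec in specimens:
            if rec.id == wanted:
                return rec
        raise KeyError(f"selector {selector!r}: no specimen with id {wanted!r}")
    if selector.startswith("class:"):
        spec = selector[len("class:") :]
        label, _, gen = spec.partition("@")
        candidates = [
            r
            for r in specimens
            if r.genotype is not None
            and phenotype(r.genotype).class_label == label
            and (not gen or r.generation == int(gen))
        ]
        if not candidates:
            raise KeyError(f"selector {selector!r} matched no specimen")
        return min(candidates, key=lambda r: r.id)
    # founder genotype code; reuse the same founder individual per code
    if selector not in founders:
        g = Genotype.from_string(selector)
        rec = SpecimenRecord(
            id=f"founder_{selector}",
            generation=0,
            genotype=g,
            m_status=phenotype(g).m_status,
            symbiont_infected=design.founders_infected.get(selector, g.mito == "a"),
        )
        founders[selector] = rec
        next_gen.append(rec)
    return founders[selector]


def simulate_design(
    design: MatingDesign,
    params: ModelParams,
    rng: np.random.Generator,
    weight_mean: float = WEIGHT_MEAN_G,
    weight_sd: float = WEIGHT_SD_G,
) -> list[SpecimenRecord]:
    """Execute a mating design cross by cross; deterministic given the seed.

    A cross whose pairing is infertile contributes zero offspring rather
    than raising.  Founders default to infected iff Ea-mito (the symbiont
    is the *E. andrei*-specific hypothesis) unless overridden in the design.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("simulate_design requires a seeded numpy Generator")
    specimens: list[SpecimenRecord] = []
    founders: dict[str, SpecimenRecord] = {}
    for idx, cross in enumerate(design.crosses):
        new_founders: list[SpecimenRecord] = []
        mother = _resolve_selector(cross.mother, specimens, founders, design, new_founders)
        father = _resolve_selector(cross.father, specimens, founders, design, new_founders)
        specimens.extend(new_founders)
        cross_params = replace(params, **cross.params) if cross.params else params
        offspring = simulate_pair(
            mother,
            father,
            cross.n_offspring,
            cross_params,
            rng,
            id_prefix=str(idx),
            weight_mean=weight_mean,
            weight_sd=weight_sd,
        )
        specimens.extend(offspring)
    return specimens


def records_to_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    """Specimen records as a DataFrame in the fixed table dialect."""
    rows = []
    for r in records:
        g = r.genotype
        rows.append(
            {
                "id": r.id,
                "generation": r.generation,
                "mother_id": r.mother_id or "",
                "father_id": r.father_id or "",
                "coi": r.coi or "",
                "nuc_mat": (r.species_diplotype or ("", ""))[0],
                "nuc_pat": (r.species_diplotype or ("", ""))[1],
                "m_mat": g.m[0] if g else "",
                "m_pat": g.m[1] if g else "",
                "m_status": r.m_status,
                "infected": "" if r.symbiont_infected is None else int(r.symbiont_infected),
                "weight_g": "" if r.body_weight_g is None else f"{r.body_weight_g:.6f}",
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def frame_to_records(df: pd.DataFrame) -> list[SpecimenRecord]:
    """Parse a specimen table back into records; genotypes only when complete."""
    out = []
    for _, row in df.iterrows():
        def clean(key: str) -> str:
            v = row.get(key, "")
            return "" if pd.isna(v) else str(v)

        m_mat, m_pat = clean("m_mat"), clean("m_pat")
        nuc_mat, nuc_pat = clean("nuc_mat"), clean("nuc_pat")
        coi = clean("coi")
        genotype = None
        if coi and nuc_mat and nuc_pat and m_mat and m_pat:
            genotype = Genotype(mito=coi, species=(nuc_mat, nuc_pat), m=(m_mat, m_pat))
        weight = clean("weight_g")
        infected = clean("infected")
        out.append(
            SpecimenRecord(
                id=str(row["id"]),
                generation=int(row["generation"]),
                mother_id=clean("mother_id") or None,
                father_id=clean("father_id") or None,
                genotype=genotype,
                coi=coi or None,
                species_diplotype=(nuc_mat, nuc_pat) if nuc_mat and nuc_pat else None,
                m_status=clean("m_status") or "unknown",
                symbiont_infected=None if infected == "" else bool(int(float(infected))),
                body_weight_g=None if weight == "" else float(weight),
            )
        )
    return out


def read_table(path: str | Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["generation"] = df["generation"].astype(int)
    return frame_to_records(df)
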