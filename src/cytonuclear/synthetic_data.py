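"""Packaged study fixture and configurable synthetic cohorts.

Two small specimen tables ship with the package:

``study_46.tsv``
    The 46 genotyped descendants of Ea x Ef founder pairs, one row per
    worm with COI haplotype, ordered 28S diplotype and observed Mp/Mn
    status.  Specimen codes reported individually (e.g. ``fFF_158/190``,
    the atypical M-positive Ef, and ``fFA_149/194``, the atypical
    M-negative hybrid) are transcribed; worms not individually coded carry
    synthetic ``_sNN`` placeholder ids.  M-locus diplotypes and pedigree
    links are unobserved and left blank.

``proof_family.tsv``
    The proof-of-concept brood: seven offspring sampled from the
    descendants of an atypical M-positive *E. fetida* (fFFMm) line, five
    Mp and two Mn.

``generate_cohort`` drives the pedigree simulator and the spectra
generator together, producing a fully synthetic study-like dataset —
specimen table, per-worm excitation/emission scans and body weights.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from cytonuclear.genotype_core import ModelParams
from cytonuclear.pedigree_sim import (
    WEIGHT_MEAN_G,
    WEIGHT_SD_G,
    MatingDesign,
    SpecimenRecord,
    study_design,
    frame_to_records,
    records_to_frame,
    simulate_design,
)
from cytonuclear.spectra import Spectrum, generate_spectrum

FIXTURE_SHA256 = {
    "study_46.tsv": "373e342fdc9fd2b24c404d66c1b94ccf860596c2a80b561a78dd611c0afe51e3",
    "proof_family.tsv": "b579a29f7fabac2c2632a744fa41324246338f94981fd0a8a375b324b69908f6",
}


def _fixture_text(name: str) -> str:
    text = resources.files("cytonuclear.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise RuntimeError(f"packaged fixture {name} was modified (sha256 {digest})")
    return text


def _load(name: str) -> list[SpecimenRecord]:
    from io import StringIO

    df = pd.read_csv(StringIO(_fixture_text(name)), sep="\t", dtype=str, keep_default_na=False)
    df["generation"] = df["generation"].astype(int)
    return frame_to_records(df)


def load_study_fixture() -> list[SpecimenRecord]:
    """The packaged 46-specimen table (hash-checked against silent edits)."""
    return _load("study_46.tsv")


def load_proof_family() -> list[SpecimenRecord]:
    """The packaged 7-offspring proof-of-concept family (mother included)."""
    return _load("proof_family.tsv")


class CohortConfig(BaseModel):
    """Configuration of a synthetic cohort run."""

    design: MatingDesign = Field(default_factory=study_design)
    params: dict = Field(default_factory=dict)
    spectra_noise_sd: float = Field(default=2.0, ge=0.0)
    weight_mean_g: float = Field(default=WEIGHT_MEAN_G, gt=0.0)
    weight_sd_g: float = Field(default=WEIGHT_SD_G, gt=0.0)


def generate_cohort(
    config: CohortConfig,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
) -> tuple[list[SpecimenRecord], dict[str, tuple[Spectrum, Spectrum]]]:
    """Simulate a design and attach synthetic spectra matching true M status.

    Returns the specimen records and, per specimen id, an
    (emission, excitation) scan pair.  When ``out_dir`` is given, writes
    ``specimens.tsv`` plus ``spectra/<id>_{em,ex}.csv`` there.
    """
    params = ModelParams(**config.params)
    records = simulate_design(
        config.design,
        params,
        rng,
        weight_mean=config.weight_mean_g,
        weight_sd=config.weight_sd_g,
    )
    scans: dict[str, tuple[Spectrum, Spectrum]] = {}
    for rec in records:
        em = generate_spectrum(rec.m_status, "emission", config.spectra_noise_sd, rng)
        ex = generate_spectrum(rec.m_status, "excitation", config.spectra_noise_sd, rng)
        scans[rec.id] = (em, ex)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "spectra").mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / "specimens.tsv", sep="\t", index=False)
        for sid, (em, ex) in scans.items():
            safe = sid.replace("/", "-")
            em.to_csv(out / "spectra" / f"{safe}_em.csv")
            ex.to_csv(out / "spectra" / f"{safe}_ex.csv")
    return records, scans
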