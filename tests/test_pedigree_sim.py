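"""Forward simulator: reproducibility, agreement with the exact enumerator,
and the symbiont transmission mechanism."""

import numpy as np
import pytest

from conftest import G
from cytonuclear.genotype_core import ModelParams, phenotype
from cytonuclear.pedigree_sim import (
    CrossSpec,
    MatingDesign,
    SpecimenRecord,
    study_design,
    read_table,
    records_to_frame,
    simulate_design,
    simulate_pair,
    transmit_symbiont,
    write_table,
)
from cytonuclear.punnett import class_distribution, pair_distribution


def founder(code, sid="m0", infected=False):
    g = G(code)
    return SpecimenRecord(id=sid, generation=0, genotype=g, m_status=phenotype(g).m_status, symbiont_infected=infected)


class TestSimulatePair:
    def test_requires_seeded_generator(self):
        with pytest.raises(TypeError):
            simulate_pair(founder("aAAMM"), founder("fFFmm", "f0"), 5, ModelParams(), rng=None)

    def test_sterile_pair_yields_no_hatchlings(self, rng):
        out = simulate_pair(founder("aAFMm"), founder("fFAmM", "f0"), 100, ModelParams(), rng)
        assert out == []

    def test_founder_pair_class_composition(self, rng):
        out = simulate_pair(founder("aAAMM"), founder("fFFmm", "f0"), 1000, ModelParams(ef_cross_success=0.0), rng)
        classes = {(phenotype(r.genotype).class_label, r.m_status) for r in out}
        assert classes <= {("Ea", "Mp"), ("Ef", "Mn"), ("hybrid_Ea_derived", "Mp")}

    def test_pedigree_links_and_coi_conservation(self, rng):
        mother, father = founder("aAAMM"), founder("fFFmm", "f0")
        by_id = {"m0": mother, "f0": father}
        out = simulate_pair(mother, father, 200, ModelParams(), rng)
        for r in out:
            # genetic roles: each partner mothers its own ova, selfed
            # offspring have father == mother
            assert r.mother_id in by_id and r.father_id in by_id
            assert r.generation == 1
            assert r.coi == by_id[r.mother_id].genotype.mito  # COI conservation
            assert r.body_weight_g > 0
        assert any(r.mother_id == "f0" for r in out)  # both partners reproduce

    def test_selfing_culture_mn_fraction(self, rng):
        # fFFMm x fFFMm: every fertilization route gives P(Mn) = 1/4
        n = 100_000
        out = simulate_pair(founder("fFFMm"), founder("fFFMm", "f0"), n, ModelParams(), rng)
        frac_mn = sum(r.m_status == "Mn" for r in out) / n
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac_mn - 0.25) < 3 * se

    def test_monte_carlo_matches_exact_distribution(self, rng):
        params = ModelParams(selfing_rate=0.4, ef_cross_success=0.2)
        n = 100_000
        out = simulate_pair(founder("aAFMm"), founder("fFFmm", "f0"), n, params, rng)
        exact = class_distribution(pair_distribution(G("aAFMm"), G("fFFmm"), params))
        observed = {}
        for r in out:
            key = (phenotype(r.genotype).class_label, r.m_status)
            observed[key] = observed.get(key, 0) + 1
        for key, p in exact.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed.get(key, 0) / n - p) < 3 * se + 1e-12, key


class TestSimulateDesign:
    def test_reproducible_byte_identical(self):
        design = study_design(40, 40)
        t1 = records_to_frame(simulate_design(design, ModelParams(), np.random.default_rng(11))).to_csv(sep="\t")
        t2 = records_to_frame(simulate_design(design, ModelParams(), np.random.default_rng(11))).to_csv(sep="\t")
        assert t1 == t2

    def test_h_zero_forbids_ef_derived_hybrids(self, rng):
        recs = simulate_design(study_design(200, 200), ModelParams(ef_cross_success=0.0), rng)
        assert all(phenotype(r.genotype).class_label != "hybrid_Ef_derived" for r in recs)

    def test_positive_h_yields_ef_derived_hybrids(self, rng):
        recs = simulate_design(study_design(300, 300), ModelParams(ef_cross_success=0.5), rng)
        assert any(phenotype(r.genotype).class_label == "hybrid_Ef_derived" for r in recs)

    def test_no_m_negative_ea_in_study_design(self, rng):
        # aAAMM x fFFmm founders cannot produce an M-negative pure-Ea worm:
        # an aAA offspring always receives at least one M from an aAAM* parent
        recs = simulate_design(study_design(300, 300), ModelParams(ef_cross_success=0.3), rng)
        assert not any(
            phenotype(r.genotype).class_label == "Ea" and r.m_status == "Mn" for r in recs
        )

    def test_empty_design_founders_only(self, rng):
        recs = simulate_design(MatingDesign(crosses=[]), ModelParams(), rng)
        assert recs == []

    def test_sterile_cross_recorded_as_zero_offspring(self, rng):
        design = MatingDesign(
            crosses=[
                CrossSpec(mother="aAFMm", father="fFAmM", n_offspring=50),
                CrossSpec(mother="aAAMM", father="fFFmm", n_offspring=10),
            ]
        )
        recs = simulate_design(design, ModelParams(), rng)
        by_gen = [r for r in recs if r.generation >= 1]
        assert all(r.mother_id in ("founder_aAAMM", "founder_fFFmm") for r in by_gen)
        assert len(by_gen) == 10

    def test_table_round_trip(self, rng, tmp_path):
        recs = simulate_design(study_design(20, 20), ModelParams(), rng)
        path = tmp_path / "table.tsv"
        write_table(recs, path)
        back = read_table(path)
        assert [r.id for r in back] == [r.id for r in recs]
        assert [str(r.genotype) for r in back] == [str(r.genotype) for r in recs]
        assert [r.m_status for r in back] == [r.m_status for r in recs]


class TestSymbiont:
    def test_infected_mother_full_vertical(self, rng):
        out = transmit_symbiont(True, False, ModelParams(symbiont_vertical_p=1.0), rng, n=50)
        assert out.all()

    def test_uninfected_parents_stay_clean(self, rng):
        out = transmit_symbiont(False, False, ModelParams(symbiont_sexual_p=1.0), rng, n=50)
        assert not out.any()

    def test_paternal_route_through_cocoon(self, rng):
        params = ModelParams(symbiont_vertical_p=1.0, symbiont_sexual_p=1.0)
        out = transmit_symbiont(False, True, params, rng, n=50)
        assert out.all()

    def test_vertical_rate_calibration(self, rng):
        params = ModelParams(symbiont_vertical_p=0.6)
        out = transmit_symbiont(True, False, params, rng, n=20_000)
        assert abs(out.mean() - 0.6) < 3 * np.sqrt(0.6 * 0.4 / 20_000)
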