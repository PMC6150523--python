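"""Classification counts, pedigree M-genotype inference, parameter
estimation and mechanism comparison."""

import math

import numpy as np
import pytest

from conftest import G
from cytonuclear.classify_infer import (
    ClassCount,
    Family,
    design_class_probs,
    estimate_params,
    grid_class_probs,
    infer_m_genotypes,
    mechanism_comparison,
    mechanism_loglik,
    tabulate,
)
from cytonuclear.genotype_core import ModelParams, phenotype
from cytonuclear.pedigree_sim import CrossSpec, MatingDesign, SpecimenRecord, study_design, simulate_design
from cytonuclear.punnett import self_distribution
from helpers_oracle import oracle_family_loglik, oracle_offspring, oracle_pair


def spec(sid, m_status, mother=None, father=None, gen=0):
    return SpecimenRecord(
        id=sid, generation=gen, mother_id=mother, father_id=father,
        coi="f", species_diplotype=("F", "F"), m_status=m_status,
    )


class TestTabulate:
    def test_empty_table(self):
        assert tabulate([]).total == 0

    def test_simulated_classification_agrees_with_phenotype(self, rng):
        recs = simulate_design(study_design(100, 100), ModelParams(), rng)
        counts = tabulate(recs)
        assert counts.total == len(recs)
        for r in recs:
            ph = phenotype(r.genotype)
            assert counts.get(ph.class_label, ph.m_status) > 0

    def test_counts_must_sum_to_total(self):
        with pytest.raises(ValueError):
            ClassCount(counts={("Ea", "Mp"): 2}, total=3)


class TestInferMGenotypes:
    def test_mp_child_of_het_by_recessive_cross(self):
        records = [
            spec("mom", "Mp"), spec("dad", "Mn"),
            spec("kid", "Mp", mother="mom", father="dad", gen=1),
        ]
        # pin the mother to Mm via an Mn sibling (she must carry an m)
        records.append(spec("sib", "Mn", mother="mom", father="dad", gen=1))
        res = infer_m_genotypes(records)
        assert res.sets["kid"] == frozenset({"Mm"})
        assert res.sets["mom"] <= frozenset({"Mm", "mM"})
        assert res.inconsistencies == []

    def test_founder_ambiguity(self):
        res = infer_m_genotypes([spec("solo", "Mp")])
        assert res.sets["solo"] == frozenset({"MM", "Mm", "mM"})

    def test_mp_parents_with_mn_child_remain_consistent(self):
        # both Mp parents may be Mm carriers, so an Mn child is legal
        records = [
            spec("mom", "Mp"), spec("dad", "Mp"),
            spec("kid", "Mn", mother="mom", father="dad", gen=1),
        ]
        assert infer_m_genotypes(records).inconsistencies == []

    def test_impossible_transmission_flagged(self):
        # an Mp worm cannot descend from two Mn (hence mm) parents
        res = infer_m_genotypes(
            [
                spec("gm1", "Mn"), spec("gm2", "Mn"),
                spec("mom", "Mp", mother="gm1", father="gm2", gen=1),
            ]
        )
        assert res.sets["mom"] == frozenset()
        assert any(sid == "mom" for sid, _ in res.inconsistencies)

    def test_truth_containment_on_simulated_pedigree(self, rng):
        recs = simulate_design(study_design(60, 60), ModelParams(), rng)
        observed = [
            SpecimenRecord(
                id=r.id, generation=r.generation, mother_id=r.mother_id,
                father_id=r.father_id, coi=r.coi, species_diplotype=r.species_diplotype,
                m_status=r.m_status,
            )
            for r in recs
        ]
        res = infer_m_genotypes(observed)
        assert res.inconsistencies == []
        for r in recs:
            assert "".join(r.genotype.m) in res.sets[r.id], r.id


class TestEstimateParams:
    def test_unobserved_ef_hybrids_push_h_to_lower_boundary(self):
        design = MatingDesign(crosses=[CrossSpec(mother="aAAMM", father="fFFmm", n_offspring=100)])
        counts = ClassCount(
            counts={("Ea", "Mp"): 25, ("hybrid_Ea_derived", "Mp"): 25, ("Ef", "Mn"): 50},
            total=100,
        )
        fit = estimate_params(counts, design, grid_points=21)
        assert fit.h_hat == 0.0
        assert not fit.flat

    def test_flat_surface_flagged_for_degenerate_design(self):
        design = MatingDesign(crosses=[CrossSpec(mother="aAAMM", father="aAAMM", n_offspring=10)])
        counts = ClassCount(counts={("Ea", "Mp"): 10}, total=10)
        fit = estimate_params(counts, design, grid_points=11)
        assert fit.flat

    def test_impossible_class_reported(self):
        design = MatingDesign(crosses=[CrossSpec(mother="aAAMM", father="aAAMM", n_offspring=10)])
        counts = ClassCount(counts={("Ef", "Mn"): 10}, total=10)
        fit = estimate_params(counts, design, grid_points=11)
        assert ("Ef", "Mn") in fit.impossible_classes

    def test_recovery_at_study_conditions(self):
        # abbreviated recovery check; the full 20-replicate experiment runs
        # in the acceptance suite
        design = MatingDesign(crosses=[CrossSpec(mother="aAAMM", father="fFFmm", n_offspring=5000)])
        sigma_grid = np.linspace(0, 1, 101)
        h_grid = np.linspace(0, 1, 101)
        surfaces = grid_class_probs(design, sigma_grid, h_grid)
        truth = design_class_probs(design, ModelParams(selfing_rate=0.5, ef_cross_success=0.1))
        keys = sorted(truth)
        rng = np.random.default_rng(7)
        draw = rng.multinomial(5000, [truth[k] for k in keys])
        counts = ClassCount(counts=dict(zip(keys, map(int, draw))), total=5000)
        fit = estimate_params(counts, design, surfaces=surfaces, sigma_grid=sigma_grid, h_grid=h_grid)
        assert abs(fit.sigma_hat - 0.5) <= 0.03
        assert abs(fit.h_hat - 0.1) <= 0.03


class TestMechanismLoglik:
    def test_mendelian_closed_form_for_proof_family(self):
        family = Family(G("fFFMm"), None, n_offspring=7, n_mn=2)
        expected = math.log(math.comb(7, 2) * 0.25**2 * 0.75**5)
        assert mechanism_loglik(family, "mendelian") == pytest.approx(expected)

    def test_pure_vertical_symbiont_cannot_explain_mn_offspring(self):
        family = Family(G("fFFMm"), None, n_offspring=7, n_mn=2, mother_infected=True)
        params = ModelParams(symbiont_vertical_p=1.0)
        assert mechanism_loglik(family, "symbiont", params) == float("-inf")
        comp = mechanism_comparison(family, params)
        assert comp["log_ratio"] > 0  # favors the Mendelian mechanism

    def test_symbiont_at_quarter_loss_matches_mendelian(self):
        family = Family(G("fFFMm"), None, n_offspring=7, n_mn=2)
        ll_mend = mechanism_loglik(family, "mendelian")
        ll_symb = mechanism_loglik(family, "symbiont", ModelParams(symbiont_vertical_p=0.75))
        assert ll_symb == pytest.approx(ll_mend)

    def test_uninfected_cocoon_yields_all_mn(self):
        family = Family(G("fFFmm"), None, n_offspring=4, n_mn=4, mother_infected=False)
        assert mechanism_loglik(family, "symbiont") == pytest.approx(0.0)
        family_bad = Family(G("fFFmm"), None, n_offspring=4, n_mn=3, mother_infected=False)
        assert mechanism_loglik(family_bad, "symbiont") == float("-inf")

    @pytest.mark.parametrize("n_mn", [0, 1, 2, 3, 4, 5])
    def test_brute_force_assignment_oracle(self, n_mn):
        # sum over all offspring genotype assignments of a 5-offspring brood
        family = Family(G("fFFMm"), None, n_offspring=5, n_mn=n_mn)
        expected = oracle_family_loglik(oracle_offspring("fFFMm", None), 5, n_mn)
        assert mechanism_loglik(family, "mendelian") == pytest.approx(expected)

    def test_pair_family_against_oracle(self):
        family = Family(G("fFFMm"), G("fFFmm"), n_offspring=4, n_mn=2)
        expected = oracle_family_loglik(oracle_pair("fFFMm", "fFFmm", sigma=0.5, h=0.1, v=0.0), 4, 2)
        assert mechanism_loglik(family, "mendelian") == pytest.approx(expected)
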