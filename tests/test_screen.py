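import io
import math

import numpy as np
import pytest

from genopheno.config import DOMINANT, RECESSIVE, GenonConfig
from genopheno.errors import SchemaError
from genopheno.scoring import UNDETERMINED, GenonResult
from genopheno.screen import (BenchmarkReport, TruthRecord, benchmark,
                              count_np, hpo_error_counts, model_moi, model_np,
                              model_score, moi_error_counts, read_truth,
                              score_pair, screen_cohort, screen_models,
                              select_positive_terms, write_truth)
from genopheno.synthetic import (PlantedAssociation, SimulationParams,
                                 simulate_cohort)
from genopheno.cohort import filter_variants

CONFIG = GenonConfig(np_cutoff=1)


@pytest.fixture(scope="module")
def planted_sim():
    params = SimulationParams(
        n_patients=400, n_background_genes=30, seed=11,
        planted=(PlantedAssociation(gene="G0003", term_id=None, moi=RECESSIVE,
                                    n_carriers_in_cases=8, phenocopy_rate=0.01),))
    sim = simulate_cohort(params)
    cohort = filter_variants(sim.cohort, CONFIG)
    return sim, cohort


class TestCountNp:
    def test_planted_biallelic_carriers_counted(self, planted_sim):
        sim, cohort = planted_sim
        truth = sim.truth[0]
        np_rec = count_np(cohort, sim.ontology, truth.gene, truth.term_id,
                          RECESSIVE, CONFIG)
        assert np_rec == 8

    def test_never_exceeds_n_cases(self, planted_sim):
        sim, cohort = planted_sim
        truth = sim.truth[0]
        from genopheno.genon import case_mask_for_term
        n_cases = int(case_mask_for_term(cohort, sim.ontology,
                                         truth.term_id).sum())
        for moi in (DOMINANT, RECESSIVE):
            assert count_np(cohort, sim.ontology, truth.gene, truth.term_id,
                            moi, CONFIG) <= n_cases

    def test_no_rare_case_carriers_zero(self, planted_sim):
        sim, cohort = planted_sim
        # a background gene against the planted term: NP recessive ~ 0
        gene = "G0010"
        value = count_np(cohort, sim.ontology, gene, sim.truth[0].term_id,
                         RECESSIVE, CONFIG)
        assert value >= 0  # well-defined


class TestScorePair:
    def test_planted_pair_recovered(self, planted_sim):
        sim, cohort = planted_sim
        truth = sim.truth[0]
        result = score_pair(cohort, sim.ontology, truth.gene, truth.term_id,
                            CONFIG)
        assert result.predicted_moi == RECESSIVE
        assert result.np_rec == 8
        assert result.hgf_rec > 5.0

    def test_deterministic(self, planted_sim):
        sim, cohort = planted_sim
        truth = sim.truth[0]
        a = score_pair(cohort, sim.ontology, truth.gene, truth.term_id, CONFIG)
        b = score_pair(cohort, sim.ontology, truth.gene, truth.term_id, CONFIG)
        assert a == b

    def test_permuted_labels_drop_hgf(self, planted_sim):
        sim, cohort = planted_sim
        truth = sim.truth[0]
        baseline = score_pair(cohort, sim.ontology, truth.gene, truth.term_id,
                              CONFIG).hgf_rec
        import copy
        drops = 0
        for perm_seed in range(20):
            rng = np.random.default_rng(perm_seed)
            shuffled = copy.deepcopy(cohort)
            term_sets = [p.hpo_terms for p in shuffled.patients]
            order = rng.permutation(len(term_sets))
            for patient, idx in zip(shuffled.patients, order):
                patient.hpo_terms = term_sets[idx]
            permuted = score_pair(shuffled, sim.ontology, truth.gene,
                                  truth.term_id, CONFIG)
            drops += permuted.hgf_rec < baseline
        assert drops >= 19  # >= 95% of 20 permutations


class TestScreenCohort:
    def test_planted_pair_ranks_first(self, planted_sim):
        sim, cohort = planted_sim
        results = screen_cohort(cohort, sim.ontology, CONFIG)
        truth = sim.truth[0]
        assert results[0].gene == truth.gene
        assert results[0].term_id == truth.term_id

    def test_np_cutoff_filters_everything(self, planted_sim):
        sim, cohort = planted_sim
        config = CONFIG.replace(np_cutoff=60)
        assert screen_cohort(cohort, sim.ontology, config) == []

    def test_raising_cutoff_never_adds_pairs(self, planted_sim):
        sim, cohort = planted_sim
        sizes = [len(screen_cohort(cohort, sim.ontology,
                                   CONFIG.replace(np_cutoff=c)))
                 for c in (1, 3, 5, 8, 20)]
        assert sizes == sorted(sizes, reverse=True)

    def test_term_allow_list(self, planted_sim):
        sim, cohort = planted_sim
        term = sim.truth[0].term_id
        results = screen_cohort(cohort, sim.ontology, CONFIG, terms=[term])
        assert results and all(r.term_id == term for r in results)

    def test_conjunction_case_set_is_intersection(self, planted_sim):
        sim, cohort = planted_sim
        from genopheno.genon import case_mask_for_term
        terms = sorted(sim.ontology.terms)
        t1, t2 = terms[1], terms[5]
        joint = case_mask_for_term(cohort, sim.ontology, (t1, t2))
        m1 = case_mask_for_term(cohort, sim.ontology, t1)
        m2 = case_mask_for_term(cohort, sim.ontology, t2)
        assert np.array_equal(joint, m1 & m2)
        results = screen_cohort(cohort, sim.ontology, CONFIG, terms=[(t1, t2)])
        label = f"{t1}&{t2}"
        assert all(r.term_id == label for r in results)
        for r in results:
            assert r.n_cases == int(joint.sum())

    def test_gene_restriction(self, planted_sim):
        sim, cohort = planted_sim
        results = screen_cohort(cohort, sim.ontology, CONFIG, genes=["G0003"])
        assert results and all(r.gene == "G0003" for r in results)

    def test_determinism(self, planted_sim):
        sim, cohort = planted_sim
        a = screen_cohort(cohort, sim.ontology, CONFIG)
        b = screen_cohort(cohort, sim.ontology, CONFIG)
        assert a == b


def _result(gene, term, hgf_dom=0.0, hgf_rec=0.0, sr_dom=1.0, sr_rec=1.0,
            np_dom=10, np_rec=10, fisher_dom=0.0, fisher_rec=0.0):
    m_dom, m_rec = hgf_dom * sr_dom, hgf_rec * sr_rec
    moi = (DOMINANT if m_dom > m_rec
           else RECESSIVE if m_rec > m_dom else UNDETERMINED)
    return GenonResult(gene, term, hgf_dom, hgf_rec, sr_dom, sr_rec,
                       m_dom, m_rec, moi, np_dom, np_rec, 50,
                       fisher_dom, fisher_rec)


class TestSelectPositiveTerms:
    def test_hand_arithmetic_oracle(self):
        # scores {2,2,2,8}: mean 3.5, sum of squared deviations 27,
        # sample variance 9, s = 3, threshold 6.5 -> only the 8 passes
        results = [_result("G", f"HP:000000{i}", hgf_dom=v)
                   for i, v in enumerate([2.0, 2.0, 2.0, 8.0])]
        assert select_positive_terms(results, CONFIG) == {"HP:0000003"}

    def test_equal_scores_select_all(self):
        results = [_result("G", f"HP:000000{i}", hgf_dom=4.0) for i in range(3)]
        assert len(select_positive_terms(results, CONFIG)) == 3

    def test_single_term_empty(self):
        assert select_positive_terms([_result("G", "HP:0000001")], CONFIG) == set()

    def test_sd_multiplier(self):
        results = [_result("G", f"HP:000000{i}", hgf_dom=v)
                   for i, v in enumerate([2.0, 2.0, 2.0, 8.0])]
        lax = CONFIG.replace(sd_multiplier=0.0)
        assert select_positive_terms(results, lax) == {"HP:0000003"}
        # threshold mean + 2s = 9.5: nothing selected
        strict = CONFIG.replace(sd_multiplier=2.0)
        assert select_positive_terms(results, strict) == set()

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValueError):
            select_positive_terms([_result("G1", "HP:0000001"),
                                   _result("G2", "HP:0000002")], CONFIG)


class TestModelAccessors:
    def test_phenogenon_uses_m_score_moi(self):
        r = _result("G", "HP:0000001", hgf_dom=10.0, hgf_rec=8.0,
                    sr_dom=0.1, sr_rec=1.0)
        assert model_moi(r, "phenogenon") == RECESSIVE
        assert model_score(r, "phenogenon") == 8.0
        assert model_np(r, "phenogenon") == r.np_rec

    def test_hgf_only_differs(self):
        r = _result("G", "HP:0000001", hgf_dom=10.0, hgf_rec=8.0,
                    sr_dom=0.1, sr_rec=1.0)
        assert model_moi(r, "hgf_only") == DOMINANT
        assert model_score(r, "hgf_only") == 10.0

    def test_fisher_model_uses_fisher_columns(self):
        r = _result("G", "HP:0000001", hgf_dom=10.0, hgf_rec=8.0,
                    fisher_dom=1.0, fisher_rec=2.0)
        assert model_moi(r, "fisher_method") == RECESSIVE
        assert model_score(r, "fisher_method") == 2.0


class TestReadTruth:
    def test_round_trip(self, tmp_path):
        records = [TruthRecord("G1", "HP:0000003", RECESSIVE),
                   TruthRecord("G2", "HP:0000004", "x-linked")]
        write_truth(records, tmp_path / "t.tsv")
        assert read_truth(str(tmp_path / "t.tsv")) == records

    def test_missing_column_named(self):
        with pytest.raises(SchemaError, match="moi"):
            read_truth(io.StringIO("gene\thpo_id\nG1\tHP:0000001\n"))

    def test_bad_moi_rejected(self):
        tsv = "gene\thpo_id\tmoi\nG1\tHP:0000001\tcodominant\n"
        with pytest.raises(SchemaError):
            read_truth(io.StringIO(tsv))

    def test_duplicate_pair_rejected(self):
        tsv = ("gene\thpo_id\tmoi\nG1\tHP:0000001\tdominant\n"
               "G1\tHP:0000001\trecessive\n")
        with pytest.raises(SchemaError):
            read_truth(io.StringIO(tsv))


class TestBenchmark:
    def _results(self):
        return {
            "phenogenon": [
                _result("G1", "HP:0000003", hgf_dom=9.0, np_dom=30),
                _result("G1", "HP:0000004", hgf_dom=2.0, np_dom=30),
                _result("G1", "HP:0000006", hgf_dom=2.0, np_dom=30),
                _result("G2", "HP:0000005", hgf_rec=7.0, np_rec=15),
                _result("G2", "HP:0000004", hgf_rec=1.0, np_rec=15),
                _result("G2", "HP:0000006", hgf_rec=1.0, np_rec=15),
            ],
        }

    def test_full_truth_zero_error(self):
        truth = [TruthRecord("G1", "HP:0000003", DOMINANT),
                 TruthRecord("G2", "HP:0000005", RECESSIVE)]
        report = benchmark(self._results(), truth, [10], [0.5], CONFIG)
        hpo = report.hpo_rows[0]
        assert hpo["error_rate"] == 0.0 and hpo["n_positive"] == 2
        moi = report.moi_rows[0]
        assert moi["error_rate"] == 0.0 and moi["n_predicted"] == 2

    def test_empty_truth_error_one(self):
        report = benchmark(self._results(), [], [10], [0.5], CONFIG)
        assert report.hpo_rows[0]["error_rate"] == 1.0

    def test_zero_evaluable_pairs_absent_not_zero(self):
        report = benchmark(self._results(), [], [999], [999.0], CONFIG)
        assert report.hpo_rows[0]["error_rate"] is None
        assert report.moi_rows[0]["error_rate"] is None

    def test_xlinked_truth_counts_as_moi_error(self):
        truth = [TruthRecord("G1", "HP:0000003", "x-linked")]
        report = benchmark(self._results(), truth, [10], [0.5], CONFIG)
        moi = report.moi_rows[0]
        assert moi["n_predicted"] == 1 and moi["n_wrong"] == 1

    def test_ontology_aware_matching(self, small_ontology):
        # prediction at the parent term counts as true against leaf truth
        results = {"phenogenon": [
            _result("G1", "HP:0000002", hgf_dom=9.0, np_dom=30),
            _result("G1", "HP:0000004", hgf_dom=1.0, np_dom=30),
            _result("G1", "HP:0000006", hgf_dom=1.0, np_dom=30),
        ]}
        truth = [TruthRecord("G1", "HP:0000003", DOMINANT)]
        report = benchmark(results, truth, [10], [], CONFIG,
                           ontology=small_ontology)
        assert report.hpo_rows[0]["error_rate"] == 0.0
        exact = benchmark(results, truth, [10], [], CONFIG.replace(
            truth_matching="exact"))
        assert exact.hpo_rows[0]["error_rate"] == 1.0

    def test_n_evaluated_monotone(self):
        results = self._results()
        report = benchmark(results, [], [5, 10, 20, 40], [], CONFIG)
        evaluated = [r["n_evaluated"] for r in report.hpo_rows
                     if r["model"] == "phenogenon"]
        assert evaluated == sorted(evaluated, reverse=True)

    def test_report_serialisation(self, tmp_path):
        truth = [TruthRecord("G1", "HP:0000003", DOMINANT)]
        report = benchmark(self._results(), truth, [10], [0.5], CONFIG)
        report.to_tsv(tmp_path / "b.tsv")
        report.to_json(tmp_path / "b.json")
        frame = report.to_frame()
        assert set(frame["curve"]) == {"hpo_error", "moi_error"}
        import json
        obj = json.loads((tmp_path / "b.json").read_text())
        assert "hpo_error" in obj and "moi_error" in obj


def test_screen_models_share_base_results(planted_sim):
    sim, cohort = planted_sim
    models = screen_models(cohort, sim.ontology, CONFIG,
                           include_recessive_af=True)
    assert models["phenogenon"] is models["hgf_only"]
    assert models["phenogenon"] is models["fisher_method"]
    assert "recessive_af" in models


def test_recessive_af_convention_changes_bins(planted_sim):
    # the comparator uses allele frequency for recessive GF: planted causal
    # variants (AF 2e-3, HOM 0) leave the rare column, weakening the signal
    sim, cohort = planted_sim
    truth = sim.truth[0]
    base = score_pair(cohort, sim.ontology, truth.gene, truth.term_id, CONFIG)
    af_config = CONFIG.replace(gf_convention="allele_frequency")
    variant = score_pair(cohort, sim.ontology, truth.gene, truth.term_id,
                         af_config)
    assert variant.hgf_rec < base.hgf_rec

    # switch off -> identical results
    again = score_pair(cohort, sim.ontology, truth.gene, truth.term_id, CONFIG)
    assert again == base
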