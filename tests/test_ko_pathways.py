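"""KO integration and pathway-completeness scoring."""

import itertools

import pytest

from aapref import ko_pathways as kp


def _koset(*triples):
    return kp.KOSet.from_rows([(g, k, s, None) for g, k, s in triples])


class TestKOSet:
    def test_duplicate_triples_stored_once(self):
        ks = _koset(("g1", "K00001", "kofamscan"), ("g1", "K00001", "kofamscan"))
        assert len(ks) == 1

    def test_multiple_kos_per_gene_retained(self):
        ks = _koset(("g1", "K00001", "kofamscan"), ("g1", "K00002", "kofamscan"))
        assert {a.ko_id for a in ks.for_gene("g1")} == {"K00001", "K00002"}

    def test_malformed_ko_rejected_with_count(self):
        ks = kp.KOSet.from_rows([("g1", "K1", "kofamscan", None),
                                 ("g2", "K00640", "kofamscan", None),
                                 ("g3", "X00001", "eggnog", None)])
        assert len(ks) == 1
        assert ks.n_rejected == 2

    def test_bad_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            kp.KOAssignment("g1", "K00001", "interpro")

    def test_table_round_trip(self, tmp_path):
        ks = _koset(("g1", "K00001", "kofamscan"), ("g2", "K00002", "eggnog"))
        path = tmp_path / "ko.tsv"
        ks.to_table(path)
        back = kp.KOSet.from_table(path)
        assert {(a.gene_id, a.ko_id, a.source) for a in back} == \
               {(a.gene_id, a.ko_id, a.source) for a in ks}


class TestIntegration:
    def test_kofam_priority_suppresses_eggnog_on_same_gene(self):
        kofam = _koset(("g1", "K01738", "kofamscan"))
        egg = _koset(("g1", "K01738", "eggnog"), ("g1", "K99999", "eggnog"))
        out = kp.integrate_ko(kofam, egg)
        assert {a.ko_id for a in out.for_gene("g1")} == {"K01738"}

    def test_eggnog_fills_unannotated_genes(self):
        kofam = _koset(("g1", "K01738", "kofamscan"))
        egg = _koset(("g2", "K00640", "eggnog"))
        out = kp.integrate_ko(kofam, egg)
        assert {a.ko_id for a in out.for_gene("g2")} == {"K00640"}

    def test_priority_merge_idempotence(self):
        kofam = _koset(("g1", "K00001", "kofamscan"), ("g2", "K00002", "kofamscan"))
        as_egg = _koset(("g1", "K00001", "eggnog"), ("g2", "K00002", "eggnog"))
        out = kp.integrate_ko(kofam, as_egg)
        assert {(a.gene_id, a.ko_id) for a in out} == \
               {(a.gene_id, a.ko_id) for a in kofam}
        assert all(a.source == "kofamscan" for a in out)

    def test_synthetic_reference_reproduces_published_set_sizes(self):
        table = kp.synthetic_reference_ko_table()
        kofam = table.subset_by_source("kofamscan")
        egg = table.subset_by_source("eggnog")
        assert len(kofam.ko_ids()) == 853
        assert len(egg.ko_ids()) == 959
        integrated = kp.integrate_ko(kofam, egg)
        assert len(integrated.ko_ids()) == 1045
        assert not integrated.has_ko(kp.MISSING_KO)


@pytest.fixture(scope="module")
def packaged():
    return kp.load_pathway_definitions()


@pytest.fixture(scope="module")
def integrated_reference():
    table = kp.synthetic_reference_ko_table()
    return kp.integrate_ko(table.subset_by_source("kofamscan"),
                           table.subset_by_source("eggnog"))


class TestPackagedDefinitions:
    def test_entry_and_step_counts(self, packaged):
        assert len(packaged) == 21
        aas = {d.amino_acid for d in packaged}
        assert len(aas) == 20
        unique_steps = {(d.amino_acid, s.step_id) for d in packaged
                        for s in d.steps}
        assert len(unique_steps) == 72

    def test_cysteine_has_two_alternative_entries(self, packaged):
        cys = [d for d in packaged if d.amino_acid == "Cys"]
        assert len(cys) == 2
        # both routes require serine O-acetyltransferase
        for d in cys:
            assert any(kp.MISSING_KO in s.alternative_kos for s in d.steps)


class TestAssessPathway:
    def test_cysteine_route_half_complete(self):
        defn = kp.PathwayDefinition("cys", "Cys", (
            kp.PathwayStep("cysE", frozenset({"K00640"})),
            kp.PathwayStep("cysK", frozenset({"K01738"})),
        ))
        rec = kp.assess_pathway(defn, _koset(("g1", "K01738", "kofamscan")))
        assert rec.completeness == 50.0
        assert rec.classification == kp.INCOMPLETE
        assert rec.missing_steps == ["cysE"]

    def test_empty_koset_gives_zero(self, packaged):
        rec = kp.assess_pathway(packaged[0], kp.KOSet())
        assert rec.completeness == 0.0

    def test_matches_presence_count_oracle_on_all_patterns(self):
        """Brute force over all 2^5 presence patterns of a 5-step pathway."""
        kos_per_step = [f"K0000{i}" for i in range(1, 6)]
        defn = kp.PathwayDefinition("toy", "Ala", tuple(
            kp.PathwayStep(f"s{i}", frozenset({ko}))
            for i, ko in enumerate(kos_per_step)))
        for pattern in itertools.product([0, 1], repeat=5):
            ks = _koset(*[(f"g{i}", ko, "kofamscan")
                          for i, (ko, p) in enumerate(zip(kos_per_step, pattern))
                          if p])
            rec = kp.assess_pathway(defn, ks)
            assert rec.n_present == sum(pattern)
            assert rec.completeness == pytest.approx(100.0 * sum(pattern) / 5)

    def test_completeness_monotone_under_koset_growth(self, packaged):
        import random
        rng = random.Random(0)
        all_kos = sorted({k for d in packaged for s in d.steps
                          for k in s.alternative_kos})
        subset = rng.sample(all_kos, 30)
        small = _koset(*[(f"g{i}", k, "kofamscan") for i, k in enumerate(subset)])
        big = _koset(*[(f"g{i}", k, "kofamscan") for i, k in enumerate(subset)],
                     *[(f"h{i}", k, "kofamscan")
                       for i, k in enumerate(rng.sample(all_kos, 40))])
        for d in packaged:
            assert (kp.assess_pathway(d, big).completeness
                    >= kp.assess_pathway(d, small).completeness)


class TestAssessAll:
    def test_reference_pattern(self, packaged, integrated_reference):
        records, summary = kp.assess_all(packaged, integrated_reference)
        assert summary.total_steps == 72
        assert summary.present_steps == 71
        assert summary.overall_pct == pytest.approx(98.6, abs=0.05)
        assert summary.n_amino_acids_complete == 19
        assert summary.auxotrophic_amino_acids == ["Cys"]
        incomplete = [r for r in records if r.classification == kp.INCOMPLETE]
        assert {r.amino_acid for r in incomplete} == {"Cys"}
        assert all(r.missing_steps == ["cysE"] for r in incomplete)

    def test_all_present_gives_100_percent(self, packaged):
        all_kos = sorted({k for d in packaged for s in d.steps
                          for k in s.alternative_kos})
        ks = _koset(*[(f"g{i}", k, "kofamscan") for i, k in enumerate(all_kos)])
        _, summary = kp.assess_all(packaged, ks)
        assert summary.overall_pct == 100.0
        assert summary.n_amino_acids_complete == 20
        assert summary.auxotrophic_amino_acids == []

    def test_summary_equals_per_pathway_hand_count(self):
        defns = [
            kp.PathwayDefinition("p1", "Ala",
                                 (kp.PathwayStep("a", frozenset({"K00001"})),
                                  kp.PathwayStep("b", frozenset({"K00002"})))),
            kp.PathwayDefinition("p2", "Gly",
                                 (kp.PathwayStep("c", frozenset({"K00003"})),)),
            kp.PathwayDefinition("p3", "Ser",
                                 (kp.PathwayStep("d", frozenset({"K00004"})),
                                  kp.PathwayStep("e", frozenset({"K00005"})))),
        ]
        ks = _koset(("g1", "K00001", "kofamscan"), ("g2", "K00003", "kofamscan"),
                    ("g3", "K00005", "kofamscan"))
        records, summary = kp.assess_all(defns, ks)
        assert summary.total_steps == 5
        assert summary.present_steps == 3
        assert sum(r.n_present for r in records) == 3

    def test_duplicate_pathway_id_rejected(self, packaged):
        with pytest.raises(ValueError, match="duplicate"):
            kp.assess_all([packaged[0], packaged[0]], kp.KOSet())
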