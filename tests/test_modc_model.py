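import pytest

from modclogic import modc
from modclogic.analysis import find_stable_states
from modclogic.network import Perturbation


MODC_MARKERS = [
    "TLR8", "TLR7", "TLR6", "TLR4", "TLR3", "NCOR2", "LY75", "CLEC4A", "CD83",
    "CD48", "CD226", "CD209", "CD1C", "CD1B", "CD1A", "THBD", "ITGAX", "CCL22", "CCL2",
]


class TestLoad:
    def test_size_and_ternary_components(self, modc_model):
        net, _ = modc_model
        assert len(net.components) >= 40
        ternary = [c.name for c in net.components if c.max_level == 2]
        assert sorted(ternary) == ["PU1", "STAT3"]
        assert [c.name for c in net.inputs] == ["CSF2", "IL4"]

    def test_marker_gene_counts(self, modc_net):
        names = {c.name for c in modc_net.components}
        _, marker_sets = modc.load_signatures()
        assert len(marker_sets["moDC"]) == 19
        assert len(marker_sets["monocyte"]) == 2
        assert len(marker_sets["macrophage"]) == 4
        for markers in marker_sets.values():
            assert set(markers) <= names

    def test_pu1_mafb_edge_is_inhibitory_at_level_2(self, modc_net):
        edge = next(
            e for e in modc_net.edges if e.source == "PU1" and e.target == "MAFB"
        )
        assert edge.sign == "-"
        assert edge.threshold == 2

    def test_every_matrix_cell_is_an_edge(self, modc_net):
        edges = {(e.source, e.target) for e in modc_net.edges}
        for fname in ("tf_by_modc_gene_matrix.tsv", "tf_by_tf_matrix.tsv"):
            mat = modc.load_interaction_fixture(fname)
            for tf in mat.index:
                for gene in mat.columns:
                    if mat.loc[tf, gene]:
                        assert (tf, gene) in edges

    def test_ledger_tags_complete(self, modc_model):
        net, ledger = modc_model
        assert ledger.tags_complete()
        assert set(ledger.calibration_clause_ids()) == set(modc.CALIBRATION_ABLATIONS)


class TestFixtureIntegrity:
    def test_irf4_targets_13_of_19_modc_genes(self):
        mat = modc.load_interaction_fixture("tf_by_modc_gene_matrix.tsv")
        assert list(mat.columns) == MODC_MARKERS
        assert mat.loc["IRF4"].sum() == 13
        assert mat.shape == (22, 19)

    def test_reported_cells_flagged(self):
        reported = modc.load_reported_cells("tf_by_modc_gene_matrix.tsv")
        assert ("PU1", "ITGAX") in reported


class TestWildType:
    def test_four_states_one_per_valuation(self, wt_states):
        assert all(len(v) == 1 for v in wt_states.values())
        assert len(wt_states) == 4

    def test_phenotype_labels(self, modc_net, wt_states):
        expected = {(0, 0): "death", (0, 1): "monocyte",
                    (1, 0): "macrophage", (1, 1): "moDC"}
        for val, states in wt_states.items():
            assert modc.classify_state(states[0], modc_net) == expected[val]

    def test_moDC_state_levels(self, modc_net, wt_states):
        """Co-stimulation drives STAT3 and PU1 to level 2 and shuts PI3K off."""
        idx = modc_net.index
        s = wt_states[(1, 1)][0]
        assert s[idx["STAT3"]] == 2
        assert s[idx["PU1"]] == 2
        assert s[idx["PI3K"]] == 0
        assert s[idx["MAFB"]] == 0

    def test_moDC_stable_state_is_fixed_point(self, modc_net, wt_states):
        s = wt_states[(1, 1)][0]
        assert modc_net.evaluate(s) == s
        assert modc_net.asynchronous_successors(s) == []

    def test_signature_components(self, modc_net, wt_states):
        idx = modc_net.index
        mono = wt_states[(0, 1)][0]
        assert all(mono[idx[m]] == 1 for m in ("KLF4", "SELL", "CD14"))
        mac = wt_states[(1, 0)][0]
        assert all(mac[idx[m]] == 1 for m in ("MAFB", "IRF8", "CCDC151", "CD206"))
        modc_state = wt_states[(1, 1)][0]
        assert all(modc_state[idx[m]] == 1 for m in ("IRF4", "STAT6", "CD1A", "CD209"))

    def test_death_state_all_zero(self, wt_states):
        assert set(wt_states[(0, 0)][0]) == {0}

    def test_wild_type_table(self, modc_net):
        table = modc.run_wild_type_analysis(modc_net)
        assert len(table) == 4
        assert list(table.phenotype) == ["death", "monocyte", "macrophage", "moDC"]

    def test_co_stimulation_never_macrophage(self, modc_net):
        """IL4 on top of CSF2 wins moDC commitment, never the macrophage fate."""
        for s in find_stable_states(modc_net, {"CSF2": 1, "IL4": 1}):
            assert modc.classify_state(s, modc_net) != "macrophage"


class TestClassification:
    def test_all_zero_is_not_misread(self, modc_net):
        assert modc.classify_state(tuple([0] * len(modc_net.components)), modc_net) == "death"

    def test_unclassified_for_arbitrary_state(self, modc_net):
        state = list([0] * len(modc_net.components))
        state[modc_net.index["KLF4"]] = 1
        assert modc.classify_state(tuple(state), modc_net) == "unclassified"

    def test_signatures_pairwise_exclusive_on_all_panel_states(self, modc_net):
        signatures, _ = modc.load_signatures()
        states = []
        for case in modc.load_perturbation_cases():
            mutant = modc_net.apply_perturbations([case.perturbation])
            for v in modc.stable_states_by_valuation(mutant).values():
                states.extend(v)
        for s in states:
            assert sum(sig.satisfied_by(modc_net, s) for sig in signatures) <= 1


class TestPerturbationPanel:
    def test_nine_cases_packaged(self):
        cases = modc.load_perturbation_cases()
        assert len(cases) == 9
        assert {c.protein for c in cases} == {
            "IRF4", "STAT6", "PU1", "IRF8", "MAFB", "NCOR2", "AHR", "JAK3", "CEBPB"
        }
        losses = [c for c in cases if c.mode == "loss"]
        assert len(losses) == 8 and all(c.perturbation.level == 0 for c in losses)

    def test_jak3_loss_gives_macrophage_under_co_stimulation(self, modc_net):
        mutant = modc_net.apply_perturbations([Perturbation("JAK3", 0)])
        states = find_stable_states(mutant, {"CSF2": 1, "IL4": 1})
        assert len(states) == 1
        assert modc.classify_state(states[0], modc_net) == "macrophage"

    def test_mafb_loss_leaves_moDC_untouched(self, modc_net, wt_states):
        mutant = modc_net.apply_perturbations([Perturbation("MAFB", 0)])
        states = find_stable_states(mutant, {"CSF2": 1, "IL4": 1})
        assert states == wt_states[(1, 1)]

    def test_stat6_gain_induces_cd209_without_il4(self, modc_net):
        mutant = modc_net.apply_perturbations([Perturbation("STAT6", 1)])
        (state,) = find_stable_states(mutant, {"CSF2": 1, "IL4": 0})
        assert state[modc_net.index["CD209"]] == 1

    def test_ncor2_loss_erases_moDC_markers(self, modc_net):
        mutant = modc_net.apply_perturbations([Perturbation("NCOR2", 0)])
        (state,) = find_stable_states(mutant, {"CSF2": 1, "IL4": 1})
        assert all(state[modc_net.index[m]] == 0 for m in MODC_MARKERS)

    def test_panel_table_labels(self, modc_net):
        panel = modc.run_perturbation_panel(
            modc_net, [Perturbation.parse("NCOR2%0")]
        )
        assert set(panel.perturbation) == {"NCOR2%0"}
        assert panel.row_label.iloc[0] == "NCOR2%0 1"
        assert len(panel) == 4  # one stable state per valuation


class TestScreen:
    def test_quartet_affects_all_three_fates(self, modc_net):
        screen = modc.run_tf_knockout_screen(modc_net)
        hit_all = set(screen.loc[screen.n_affected == 3, "tf"])
        assert hit_all == {"BATF3", "FOXO1", "PU1", "USF1"}

    def test_screen_covers_every_matrix_tf_once(self, modc_net):
        screen = modc.run_tf_knockout_screen(modc_net)
        tfs = list(modc.load_interaction_fixture("tf_by_modc_gene_matrix.tsv").index)
        assert list(screen.tf) == tfs
        assert screen.tf.is_unique

    def test_tf_without_outgoing_edges_affects_nothing(self, modc_net):
        # EGR2 regulates no other component in the model
        assert not any(e.source == "EGR2" for e in modc_net.edges)
        screen = modc.run_tf_knockout_screen(modc_net)
        assert screen.set_index("tf").loc["EGR2", "n_affected"] == 0


class TestValidator:
    def test_packaged_model_passes_all_constraints(self, modc_net):
        report = modc.validate_model(modc_net)
        assert report.passed, report.failures()

    def test_empty_constraint_list_trivially_passes(self, modc_net):
        report = modc.validate_model(
            modc_net, cases=[], include_trap_spaces=False, include_screen=False
        )
        assert report.passed

    def test_removing_pu1_threshold_edge_breaks_calibration(self):
        """Without the PU1-level-2 switch-off, MAFB persists in the moDC state."""
        ablated = modc.ablate_calibration_clause("mafb_pu1_repression")
        report = modc.validate_model(
            ablated, include_trap_spaces=False, include_screen=False
        )
        assert not report.passed
        assert any("moDC" in c for c, _ in report.failures())

    @pytest.mark.parametrize("clause_id", sorted(modc.CALIBRATION_ABLATIONS))
    def test_every_calibration_clause_is_load_bearing(self, clause_id):
        """Ablating any single calibration clause violates >= 1 constraint."""
        ablated = modc.ablate_calibration_clause(clause_id)
        report = modc.validate_model(ablated, include_trap_spaces=False)
        assert not report.passed
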