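"""The packaged monocyte → moDC differentiation model and its analyses.

The model couples the CSF2 and IL4 signalling branches (NFKB/MAPK/PI3K/JAK2/
STAT5 and JAK1-STAT3 / JAK3-STAT6) to a transcription-factor layer and the
cell-type marker genes, with two ternary components (STAT3 and PU1) whose
high levels mark moDC commitment.  Under free inputs it has exactly four
stable states — cell death (no stimulus), activated monocyte (IL4),
macrophage (CSF2) and moDC (CSF2+IL4).

Every edge and rule clause ships with a provenance tag (literature /
epigenomics-predicted / calibration).  Calibration clauses are registered
here with a machine ablation each, so the validator can demonstrate that
every one of them is load-bearing.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .analysis import find_minimal_trap_spaces, find_stable_states
from .io import ModelProvenanceLedger, document_to_model, read_interaction_matrix
from .network import LogicalNetwork, Perturbation, State

INPUTS = ("CSF2", "IL4")
INPUT_VALUATIONS = ((0, 0), (0, 1), (1, 0), (1, 1))
SCREEN_QUARTET = frozenset({"BATF3", "FOXO1", "PU1", "USF1"})


def _data_path(name: str):
    return resources.files("modclogic.data").joinpath(name)


def load_modc_document() -> dict:
    with _data_path("modc_network.json").open() as fh:
        return json.load(fh)


def load_modc_model() -> tuple[LogicalNetwork, ModelProvenanceLedger]:
    """The packaged differentiation model plus its provenance ledger.

    Integrity is checked on load: schema validation, rule/edge sign
    consistency, and presence of an edge for every cell of the transcribed
    interaction matrices.
    """
    network, ledger = document_to_model(load_modc_document())
    edge_set = {(e.source, e.target) for e in network.edges}
    for matrix_name in ("tf_by_modc_gene_matrix.tsv", "tf_by_tf_matrix.tsv"):
        mat = load_interaction_fixture(matrix_name)
        for tf in mat.index:
            for gene in mat.columns:
                if mat.loc[tf, gene] and (tf, gene) not in edge_set:
                    raise ValueError(
                        f"packaged-data integrity: matrix cell {tf}->{gene} "
                        f"({matrix_name}) has no corresponding edge"
                    )
    return network, ledger


def load_interaction_fixture(name: str) -> pd.DataFrame:
    """A packaged TF x gene matrix; asterisked (previously reported) cells
    are returned as 1 with the flags available via ``load_reported_cells``."""
    with _data_path(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
    return df.map(lambda v: 1 if str(v).startswith("1") else 0)


def load_reported_cells(name: str) -> set[tuple[str, str]]:
    with _data_path(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
    return {
        (tf, gene)
        for tf in df.index
        for gene in df.columns
        if str(df.loc[tf, gene]).endswith("*")
    }


# ---------------------------------------------------------------------------
# phenotype signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSignature:
    """Required ON/OFF/exact-level constraints defining one cell-fate label."""

    label: str
    on: tuple[str, ...] = ()
    off: tuple[str, ...] = ()
    exact: tuple[tuple[str, int], ...] = ()
    inputs: tuple[tuple[str, int], ...] = ()

    def satisfied_by(self, network: LogicalNetwork, state: State) -> bool:
        idx = network.index
        return (
            all(state[idx[n]] >= 1 for n in self.on)
            and all(state[idx[n]] == 0 for n in self.off)
            and all(state[idx[n]] == v for n, v in self.exact)
            and all(state[idx[n]] == v for n, v in self.inputs)
        )


def load_signatures() -> tuple[list[PhenotypeSignature], dict[str, list[str]]]:
    """Packaged signatures and the per-lineage marker sets."""
    with _data_path("phenotype_signatures.json").open() as fh:
        doc = json.load(fh)
    sigs = []
    for label, spec in doc["signatures"].items():
        sigs.append(
            PhenotypeSignature(
                label,
                tuple(spec.get("on", ())),
                tuple(spec.get("off", ())),
                tuple(sorted(spec.get("exact", {}).items())),
                tuple(sorted(spec.get("inputs", {}).items())),
            )
        )
    return sigs, doc["marker_sets"]


def classify_state(
    state: State,
    network: LogicalNetwork | None = None,
    signatures: list[PhenotypeSignature] | None = None,
) -> str:
    """The unique phenotype signature a state satisfies, else "unclassified"."""
    if network is None:
        network, _ = load_modc_model()
    if signatures is None:
        signatures, _ = load_signatures()
    matches = [s.label for s in signatures if s.satisfied_by(network, state)]
    return matches[0] if len(matches) == 1 else "unclassified"


# ---------------------------------------------------------------------------
# documented mutant cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationCase:
    """One documented mutant: the clamp and its expected qualitative outcome."""

    protein: str
    perturbation: Perturbation
    mode: str
    model_phenotype: str
    checks: tuple[dict, ...]


def load_perturbation_cases() -> list[PerturbationCase]:
    with _data_path("perturbation_cases.json").open() as fh:
        doc = json.load(fh)
    return [
        PerturbationCase(
            c["protein"],
            Perturbation.parse(c["perturbation"]),
            c["mode"],
            c["model_phenotype"],
            tuple(c["checks"]),
        )
        for c in doc
    ]


# ---------------------------------------------------------------------------
# wild-type analysis
# ---------------------------------------------------------------------------

def stable_states_by_valuation(
    network: LogicalNetwork,
) -> dict[tuple[int, int], list[State]]:
    out = {}
    for csf2, il4 in INPUT_VALUATIONS:
        clamp = {}
        if not network.clamps or "CSF2" not in network.clamps:
            clamp["CSF2"] = csf2
        if not network.clamps or "IL4" not in network.clamps:
            clamp["IL4"] = il4
        out[(csf2, il4)] = find_stable_states(network, clamp)
    return out


def run_wild_type_analysis(network: LogicalNetwork | None = None) -> pd.DataFrame:
    """One row per input valuation: the stable state and its phenotype label."""
    if network is None:
        network, _ = load_modc_model()
    signatures, _ = load_signatures()
    names = [c.name for c in network.components]
    rows = []
    for (csf2, il4), states in stable_states_by_valuation(network).items():
        for k, state in enumerate(states):
            row = {"CSF2": csf2, "IL4": il4, "state_index": k,
                   "phenotype": classify_state(state, network, signatures)}
            row.update({n: v for n, v in zip(names, state)})
            rows.append(row)
    return pd.DataFrame(rows)


def run_perturbation_panel(
    network: LogicalNetwork | None = None,
    perturbations: list[Perturbation] | None = None,
) -> pd.DataFrame:
    """Long-format stable-state table for clamped variants of the model.

    Rows are labelled ``"NAME%LEVEL k"`` with k the 1-based index of the
    stable state obtained under that clamp and input valuation.
    """
    if network is None:
        network, _ = load_modc_model()
    if perturbations is None:
        perturbations = [c.perturbation for c in load_perturbation_cases()]
    signatures, _ = load_signatures()
    names = [c.name for c in network.components]
    rows = []
    for pert in perturbations:
        mutant = network.apply_perturbations([pert])
        for (csf2, il4), states in stable_states_by_valuation(mutant).items():
            for k, state in enumerate(states):
                row = {
                    "perturbation": pert.label,
                    "row_label": f"{pert.label} {k + 1}",
                    "CSF2": csf2,
                    "IL4": il4,
                    "phenotype": classify_state(state, network, signatures),
                }
                row.update({n: v for n, v in zip(names, state)})
                rows.append(row)
    return pd.DataFrame(rows)


def run_tf_knockout_screen(network: LogicalNetwork | None = None) -> pd.DataFrame:
    """Knock out every TF of the interaction-matrix row set.

    For each TF, reports which of the three non-death wild-type stable states
    change in any component *other than the clamped TF itself* (otherwise
    every expressed TF would trivially affect every state).
    """
    if network is None:
        network, _ = load_modc_model()
    tfs = list(load_interaction_fixture("tf_by_modc_gene_matrix.tsv").index)
    wt = stable_states_by_valuation(network)
    lineages = {(0, 1): "monocyte", (1, 0): "macrophage", (1, 1): "moDC"}
    rows = []
    for tf in tfs:
        i = network.index[tf]
        mutant = network.apply_perturbations([Perturbation(tf, 0)])
        mut = stable_states_by_valuation(mutant)
        affected = {}
        for val, lineage in lineages.items():
            wt_states = [s[:i] + s[i + 1 :] for s in wt[val]]
            mut_states = [s[:i] + s[i + 1 :] for s in mut[val]]
            affected[lineage] = wt_states != mut_states
        rows.append(
            {
                "tf": tf,
                "affects_monocyte": affected["monocyte"],
                "affects_macrophage": affected["macrophage"],
                "affects_moDC": affected["moDC"],
                "n_affected": sum(affected.values()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Machine-checkable constraint results; failures are data, not errors."""

    results: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, constraint: str, passed: bool, detail: str = ""):
        self.results.append((constraint, bool(passed), detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.results)

    def failures(self) -> list[tuple[str, str]]:
        return [(c, d) for c, ok, d in self.results if not ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.results, columns=["constraint", "passed", "detail"])


_EXPECTED_LABELS = {(0, 0): "death", (0, 1): "monocyte", (1, 0): "macrophage", (1, 1): "moDC"}


def _check_case(network, signatures, marker_sets, wt_states, case) -> list[tuple[str, bool, str]]:
    mutant = network.apply_perturbations([case.perturbation])
    mut_states = stable_states_by_valuation(mutant)
    idx = network.index
    out = []
    for j, check in enumerate(case.checks):
        val = (check["csf2"], check["il4"])
        states = mut_states[val]
        cid = f"mutant_panel[{case.perturbation.label}][{j}:{check['type']}@{val}]"
        if not states:
            out.append((cid, False, "no stable state under this valuation"))
            continue
        ok, detail = True, ""
        for state in states:
            if check["type"] == "classify_equals":
                label = classify_state(state, network, signatures)
                if label != check["label"]:
                    ok, detail = False, f"classified {label!r}"
            elif check["type"] == "classify_not":
                label = classify_state(state, network, signatures)
                if label == check["label"]:
                    ok, detail = False, f"classified {label!r}"
            elif check["type"] == "component_equals":
                v = state[idx[check["component"]]]
                if v != check["level"]:
                    ok, detail = False, f"{check['component']}={v}"
            elif check["type"] in ("markers_all_off", "markers_off_at_least", "markers_on_at_least"):
                markers = marker_sets[check["lineage"]]
                n_off = sum(state[idx[m]] == 0 for m in markers)
                n_on = len(markers) - n_off
                if check["type"] == "markers_all_off" and n_off != len(markers):
                    ok, detail = False, f"{n_on} markers still on"
                if check["type"] == "markers_off_at_least" and n_off < check["count"]:
                    ok, detail = False, f"only {n_off} markers off"
                if check["type"] == "markers_on_at_least" and n_on < check["count"]:
                    ok, detail = False, f"only {n_on} markers on"
            elif check["type"] == "state_equals_wild_type":
                i = idx[case.perturbation.component]
                ref = [s[:i] + s[i + 1 :] for s in wt_states[val]]
                got = [s[:i] + s[i + 1 :] for s in states]
                if ref != got:
                    ok, detail = False, "perturbed stable state differs from wild type"
            else:
                ok, detail = False, f"unknown check type {check['type']!r}"
        out.append((cid, ok, detail))
    return out


def validate_model(
    network: LogicalNetwork | None = None,
    signatures: list[PhenotypeSignature] | None = None,
    cases: list[PerturbationCase] | None = None,
    include_trap_spaces: bool = True,
    include_screen: bool = True,
) -> ValidationReport:
    """Regression harness for the model's calibration constraints.

    Checks (a) the wild-type stable-state table (count, classification,
    ternary levels, lineage-marker exclusivity), (b) every packaged mutant
    case, (c) trap-space purity, and (d) the four-TF knock-out screen claim.
    """
    if network is None:
        network, _ = load_modc_model()
    if signatures is None:
        signatures, marker_sets = load_signatures()
    else:
        _, marker_sets = load_signatures()
    if cases is None:
        cases = load_perturbation_cases()
    report = ValidationReport()
    idx = network.index

    wt = stable_states_by_valuation(network)
    report.add(
        "wild_type.one_state_per_valuation",
        all(len(v) == 1 for v in wt.values()),
        str({k: len(v) for k, v in wt.items()}),
    )
    all_states = [s for v in wt.values() for s in v]
    report.add("wild_type.four_states_total", len(set(all_states)) == 4)
    for val, states in wt.items():
        for state in states:
            label = classify_state(state, network, signatures)
            report.add(
                f"wild_type.label@{val}",
                label == _EXPECTED_LABELS[val],
                f"classified {label!r}",
            )
    if wt[(1, 1)]:
        modc = wt[(1, 1)][0]
        for comp, lev in (("STAT3", 2), ("PU1", 2), ("PI3K", 0), ("MAFB", 0)):
            report.add(
                f"wild_type.moDC.{comp}={lev}",
                modc[idx[comp]] == lev,
                f"{comp}={modc[idx[comp]]}",
            )
    if wt[(0, 0)]:
        report.add("wild_type.death_all_zero", set(wt[(0, 0)][0]) == {0})
    # lineage markers are exclusive to their own state
    own_val = {"monocyte": (0, 1), "macrophage": (1, 0), "moDC": (1, 1)}
    for lineage, markers in marker_sets.items():
        for val, states in wt.items():
            for state in states:
                on = [m for m in markers if state[idx[m]] >= 1]
                if val == own_val[lineage]:
                    report.add(
                        f"wild_type.markers_on.{lineage}@{val}",
                        len(on) == len(markers),
                        f"{len(on)}/{len(markers)} on",
                    )
                else:
                    report.add(
                        f"wild_type.markers_off.{lineage}@{val}",
                        not on,
                        f"unexpected ON markers {on}" if on else "",
                    )

    # signature exclusivity over wild-type and panel states
    panel_states = list(all_states)
    for case in cases:
        mutant = network.apply_perturbations([case.perturbation])
        for states in stable_states_by_valuation(mutant).values():
            panel_states.extend(states)
        for item in _check_case(network, signatures, marker_sets, wt, case):
            report.add(*item)
    multi = [
        s for s in panel_states
        if sum(sig.satisfied_by(network, s) for sig in signatures) > 1
    ]
    report.add(
        "signatures.pairwise_exclusive",
        not multi,
        f"{len(multi)} states satisfy more than one signature" if multi else "",
    )

    if include_trap_spaces:
        traps = find_minimal_trap_spaces(network)
        report.add(
            "trap_spaces.all_single_states",
            all(t.is_state() for t in traps),
            f"{sum(not t.is_state() for t in traps)} non-singleton trap spaces",
        )
        report.add(
            "trap_spaces.match_stable_states",
            sorted(t.to_state() for t in traps if t.is_state()) == sorted(all_states),
        )

    if include_screen:
        screen = run_tf_knockout_screen(network)
        hit_all = set(screen.loc[screen.n_affected == 3, "tf"])
        report.add(
            "screen.quartet_affects_all_three",
            hit_all == set(SCREEN_QUARTET),
            f"TFs affecting all three states: {sorted(hit_all)}",
        )
    return report


# ---------------------------------------------------------------------------
# calibration-clause ablations
# ---------------------------------------------------------------------------

# Each calibration clause id maps to a transformation of the model document
# that removes just that modelling decision (reverting the touched rules to
# the plain OR-of-predicted-activators convention where applicable).  The
# validator must fail on every ablated model: the calibration set is minimal.
CALIBRATION_ABLATIONS: dict[str, dict[str, list[tuple[str, int]]]] = {
    "pi3k_stat6_inhibition": {"PI3K": [("CSF2", 1)]},
    "lncdc_pu1_induction": {"LNCDC": []},
    "pu1_level2_costimulation": {"PU1": [("STAT5 | STAT3", 1)]},
    "pu1_il4_maintenance": {
        "PU1": [("STAT5 & !(STAT5 & STAT6)", 1), ("STAT5 & STAT6", 2)]
    },
    "irf4_coincidence": {"IRF4": [("STAT6 | NFKB | AHR | PU1:1", 1)]},
    "klf4_irf4_repression": {"KLF4": [("IRF8 & !MAFB", 1)]},
    "klf4_mafb_repression": {"KLF4": [("IRF8 & !IRF4", 1)]},
    "mafb_irf8_requirement": {"MAFB": [("STAT5 & !PU1:2", 1)]},
    "mafb_pu1_repression": {"MAFB": [("STAT5 & IRF8", 1)]},
    "ahr_il4_activation": {"AHR": []},
    "cebpa_stat6_activation": {"CEBPA": []},
    "prdm1_csf2_gating": {"PRDM1": [("AHR", 1)]},
    "ncor2_prdm1_activation": {"NCOR2": [("IRF4", 1)]},
    "ncor2_coactivation": {
        "TLR8": [("STAT6", 1)],
        "TLR7": [("IRF4", 1)],
        "TLR6": [("STAT6 | FOXO1", 1)],
        "TLR4": [("IRF4", 1)],
        "TLR3": [("IRF4", 1)],
        "LY75": [("IRF4", 1)],
        "CLEC4A": [("FOXO1", 1)],
        "CD83": [("IRF4 & USF1", 1)],
        "CD48": [("PU1:1 | FOXO1 | CEBPA", 1)],
        "CD226": [("IRF4", 1)],
        "CD209": [("IRF4 & BATF3", 1)],
        "CD1C": [("IRF4", 1)],
        "CD1B": [("IRF4", 1)],
        "CD1A": [("IRF4", 1)],
        "THBD": [("CEBPA", 1)],
        "ITGAX": [("IRF4", 1)],
        "CCL22": [("IRF4", 1)],
        "CCL2": [("FOXO1 | CEBPA", 1)],
    },
    "irf4_necessity": {
        "TLR4": [("(IRF4 | AP1 | CEBPA | FOXO1) & NCOR2", 1)],
        "LY75": [("(IRF4 | AP1 | FOXO1) & NCOR2", 1)],
        "CD83": [("(IRF4 | USF1) & NCOR2", 1)],
        "CD226": [("(IRF4 | BATF3) & NCOR2", 1)],
        "CD209": [("(IRF4 | AP1 | BATF3) & NCOR2", 1)],
        "CD1A": [("(IRF4 | CEBPA | CREB | PRDM1 | PU1:1) & NCOR2", 1)],
        "CD1B": [("(IRF4 | CEBPA | PRDM1 | PU1:1) & NCOR2", 1)],
        "CD1C": [("(IRF4 | CEBPA | NR4A1 | PRDM1 | PU1:1) & NCOR2", 1)],
        "ITGAX": [("(IRF4 | PU1:1) & NCOR2", 1)],
    },
    "usf1_licensing": {
        "CD83": [("IRF4 & NCOR2", 1)],
        "CD14": [("KLF4 & BATF3", 1)],
        "MERTK": [("MAFB & CEBPB", 1)],
    },
    "batf3_licensing": {
        "CD209": [("IRF4 & NCOR2", 1)],
        "CD14": [("KLF4 & USF1", 1)],
        "CD206": [("MAFB", 1)],
    },
    "foxo1_licensing": {
        "SELL": [("KLF4", 1)],
        "CD163": [("MAFB & CEBPB", 1)],
    },
    "cebpb_requirement": {
        "CD163": [("MAFB & FOXO1", 1)],
        "MERTK": [("MAFB & USF1", 1)],
    },
    "usf1_activation": {"USF1": []},
    "batf3_activation": {"BATF3": []},
    "foxo1_activation": {"FOXO1": []},
}


def ablate_calibration_clause(clause_id: str) -> LogicalNetwork:
    """The packaged model with one calibration clause removed."""
    if clause_id not in CALIBRATION_ABLATIONS:
        raise KeyError(f"unknown calibration clause {clause_id!r}")
    doc = copy.deepcopy(load_modc_document())
    for comp, new_rules in CALIBRATION_ABLATIONS[clause_id].items():
        doc["rules"][comp] = [
            {"condition": cond, "target": tgt} for cond, tgt in new_rules
        ]
    network, _ = document_to_model(doc, check_edges=False)
    return network
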