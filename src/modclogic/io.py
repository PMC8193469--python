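"""Model serialization (JSON dialect) and sequence/matrix file helpers.

The model document is a human-diffable JSON object::

    {
      "format_version": 1,
      "components": [{"name": "PU1", "max_level": 2, "is_input": false}, ...],
      "rules": {"PU1": [{"condition": "STAT5 & STAT6", "target": 2,
                         "tag": "calibration", "note": "...", "clauses": ["id"]}, ...]},
      "edges": [{"source": "PU1", "target": "MAFB", "sign": "-", "threshold": 2,
                 "tag": "calibration", "note": "..."}, ...]
    }

Conditions use the literal dialect of :mod:`modclogic.expressions`
(``"PU1:2 & !MAFB"`` = PU1 >= 2 AND NOT MAFB).  Provenance tags are
``literature``, ``predicted`` (epigenomics-predicted) or ``calibration``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .expressions import ExpressionError, parse_condition
from .network import Component, Edge, LogicalNetwork, RuleClause

FORMAT_VERSION = 1
PROVENANCE_TAGS = ("literature", "predicted", "calibration")


class ModelFormatError(ValueError):
    """Schema violation in a model document; the message names the field."""


@dataclass(frozen=True)
class ProvenanceEntry:
    kind: str  # "edge" or "clause"
    key: str  # "SRC->TGT" or "COMPONENT[i]"
    tag: str
    note: str = ""
    clauses: tuple[str, ...] = ()  # calibration-clause ids, when applicable


@dataclass
class ModelProvenanceLedger:
    """Per-edge / per-rule-clause source annotations of a packaged model."""

    entries: list[ProvenanceEntry] = field(default_factory=list)

    def calibration_entries(self) -> list[ProvenanceEntry]:
        return [e for e in self.entries if e.tag == "calibration"]

    def calibration_clause_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.tag == "calibration":
                for cid in e.clauses:
                    seen.setdefault(cid)
        return list(seen)

    def tags_complete(self) -> bool:
        return all(e.tag in PROVENANCE_TAGS for e in self.entries)


def model_to_document(
    network: LogicalNetwork, ledger: ModelProvenanceLedger | None = None
) -> dict:
    """Render a network (plus optional ledger annotations) as a JSON document."""
    notes = {}
    if ledger:
        notes = {(e.kind, e.key): e for e in ledger.entries}
    doc: dict = {"format_version": FORMAT_VERSION, "components": [], "rules": {}, "edges": []}
    for c in network.components:
        doc["components"].append(
            {"name": c.name, "max_level": c.max_level, "is_input": c.is_input}
        )
    for name, clauses in network.rules.items():
        out = []
        for i, cl in enumerate(clauses):
            entry = {"condition": str(cl.condition), "target": cl.target}
            ann = notes.get(("clause", f"{name}[{i}]"))
            if ann:
                entry["tag"] = ann.tag
                if ann.note:
                    entry["note"] = ann.note
                if ann.clauses:
                    entry["clauses"] = list(ann.clauses)
            out.append(entry)
        doc["rules"][name] = out
    for e in network.edges:
        entry = {"source": e.source, "target": e.target, "sign": e.sign, "threshold": e.threshold}
        ann = notes.get(("edge", f"{e.source}->{e.target}"))
        if ann:
            entry["tag"] = ann.tag
            if ann.note:
                entry["note"] = ann.note
        doc["edges"].append(entry)
    return doc


def document_to_model(
    doc: dict, check_edges: bool = True
) -> tuple[LogicalNetwork, ModelProvenanceLedger]:
    """Validate a model document and build the network plus its ledger."""
    if not isinstance(doc, dict):
        raise ModelFormatError("model document must be a JSON object")
    if doc.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"format_version: expected {FORMAT_VERSION}, got {doc.get('format_version')!r}"
        )
    comps = []
    for i, c in enumerate(doc.get("components", [])):
        for key in ("name",):
            if key not in c:
                raise ModelFormatError(f"components[{i}]: missing field {key!r}")
        comps.append(
            Component(c["name"], int(c.get("max_level", 1)), bool(c.get("is_input", False)))
        )
    names = {c.name for c in comps}
    entries: list[ProvenanceEntry] = []
    rules: dict[str, list[RuleClause]] = {}
    for name, clauses in doc.get("rules", {}).items():
        if name not in names:
            raise ModelFormatError(f"rules: unknown component {name!r}")
        parsed = []
        for i, cl in enumerate(clauses):
            if "condition" not in cl or "target" not in cl:
                raise ModelFormatError(f"rules[{name}][{i}]: needs 'condition' and 'target'")
            try:
                cond = parse_condition(cl["condition"])
            except ExpressionError as exc:
                raise ModelFormatError(f"rules[{name}][{i}]: {exc}") from exc
            for ref in cond.support():
                if ref not in names:
                    raise ModelFormatError(
                        f"rules[{name}][{i}]: condition references unknown component {ref!r}"
                    )
            parsed.append(RuleClause(cond, int(cl["target"])))
            if "tag" in cl:
                if cl["tag"] not in PROVENANCE_TAGS:
                    raise ModelFormatError(f"rules[{name}][{i}]: unknown tag {cl['tag']!r}")
                entries.append(
                    ProvenanceEntry(
                        "clause", f"{name}[{i}]", cl["tag"], cl.get("note", ""),
                        tuple(cl.get("clauses", ())),
                    )
                )
        rules[name] = parsed
    edges = []
    for i, e in enumerate(doc.get("edges", [])):
        for key in ("source", "target"):
            if key not in e:
                raise ModelFormatError(f"edges[{i}]: missing field {key!r}")
        edges.append(
            Edge(e["source"], e["target"], e.get("sign", "+"), int(e.get("threshold", 1)))
        )
        if "tag" in e:
            if e["tag"] not in PROVENANCE_TAGS:
                raise ModelFormatError(f"edges[{i}]: unknown tag {e['tag']!r}")
            entries.append(
                ProvenanceEntry(
                    "edge", f"{e['source']}->{e['target']}", e["tag"], e.get("note", "")
                )
            )
    network = LogicalNetwork(comps, rules, edges, check_edges=check_edges)
    return network, ModelProvenanceLedger(entries)


def read_model(path: str | Path) -> tuple[LogicalNetwork, ModelProvenanceLedger]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    return document_to_model(doc)


def write_model(
    network: LogicalNetwork, path: str | Path, ledger: ModelProvenanceLedger | None = None
) -> None:
    doc = model_to_document(network, ledger)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# sequences and matrices
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_jaspar_pfm(path: str | Path):
    """Read JASPAR-formatted position frequency matrices.

    Returns a list of (motif_id, counts) where counts is a 4 x w array in
    A, C, G, T row order.
    """
    import numpy as np
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append((m.matrix_id or m.name, counts))
    return out


def read_interaction_matrix(path: str | Path):
    """Read a TF x gene 0/1 TSV matrix (rows TFs) into a pandas DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(int)
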