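"""Synthetic inputs: random logical networks and promoter-like sequences.

The network generator draws random signed digraphs and equips them with the
default rule convention of the study ("any activator is sufficient provided
all inhibitors are absent"), so the generated rule class matches the packaged
model's; it feeds the exact-engine oracle tests.  The sequence generator
emits Markov-1 background with motif-distributed sites planted at known
coordinates (overwriting the background, so coordinates stay stable) and is
the ground truth for scanner benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expressions import And, Literal, Not, Or, parse_condition
from .motifs import BASES, MarkovBackground, decode_sequence, reverse_complement
from .network import Component, Edge, LogicalNetwork, RuleClause


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# random logical networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkGenSpec:
    """Specification of a random-network draw (same spec + seed => same net)."""

    n: int
    max_in_degree: int = 3
    p_inhibitory: float = 0.3
    ternary_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise GenerationError("n must be >= 1")
        if self.max_in_degree < 0 or self.max_in_degree >= self.n + 1:
            pass  # in-degree is clipped to available regulators below
        for p in (self.p_inhibitory, self.ternary_fraction):
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must lie in [0, 1]")


def random_network(spec: NetworkGenSpec) -> LogicalNetwork:
    """Draw a random multilevel logical network under the default convention.

    Components with no regulators carry the empty rule (constant 0).
    Activators enter an OR; a ternary target reaches level 2 when *all* its
    activators are active, level 1 when only some are; inhibitors must all be
    absent for any activation.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"X{i:02d}" for i in range(spec.n)]
    max_levels = {
        name: 2 if rng.random() < spec.ternary_fraction else 1 for name in names
    }
    components = [Component(name, max_levels[name]) for name in names]
    rules: dict[str, list[RuleClause]] = {}
    edges: list[Edge] = []
    for name in names:
        k = int(rng.integers(0, min(spec.max_in_degree, spec.n) + 1))
        if k == 0:
            rules[name] = []
            continue
        regulators = [str(r) for r in rng.choice(names, size=k, replace=False)]
        activators: list[Literal] = []
        inhibitors: list[Literal] = []
        for reg in regulators:
            threshold = int(rng.integers(1, max_levels[reg] + 1))
            lit = Literal(reg, threshold)
            if rng.random() < spec.p_inhibitory:
                inhibitors.append(lit)
                edges.append(Edge(reg, name, "-", threshold))
            else:
                activators.append(lit)
                edges.append(Edge(reg, name, "+", threshold))
        no_inh = tuple(Not(l) for l in inhibitors)
        top = max_levels[name]
        if not activators:
            # repressor-only component: basally at its maximum
            clauses = [RuleClause(And(no_inh), top)]
        elif top == 1 or len(activators) == 1:
            any_on = activators[0] if len(activators) == 1 else Or(tuple(activators))
            cond = And((any_on,) + no_inh) if no_inh else any_on
            clauses = [RuleClause(cond, top)]
        else:
            all_on = And(tuple(activators))
            any_on = Or(tuple(activators))
            full = And((all_on,) + no_inh)
            partial = And((any_on, Not(all_on)) + no_inh)
            clauses = [RuleClause(partial, 1), RuleClause(full, 2)]
        # normalize to print-stable form so serialization round-trips exactly
        rules[name] = [
            RuleClause(parse_condition(str(c.condition)), c.target) for c in clauses
        ]
    return LogicalNetwork(components, rules, edges)


# ---------------------------------------------------------------------------
# promoter-like sequences with planted sites
# ---------------------------------------------------------------------------

# A mildly structured default background: GC-biased with CpG depletion, the
# gross statistical texture of promoter-proximal regions.
DEFAULT_PROMOTER_TRANSITIONS = np.array(
    [
        [0.30, 0.21, 0.28, 0.21],
        [0.32, 0.30, 0.08, 0.30],
        [0.25, 0.25, 0.30, 0.20],
        [0.18, 0.24, 0.29, 0.29],
    ]
)


def default_promoter_background() -> MarkovBackground:
    t = DEFAULT_PROMOTER_TRANSITIONS
    bg = MarkovBackground(np.full(4, 0.25), t)
    return MarkovBackground(bg.stationary(), t)


def strong_motif_counts(
    width: int = 15, seed: int = 0, dominant: int = 27, total: int = 30
) -> np.ndarray:
    """Counts of a high-information motif (one dominant base per position)."""
    rng = np.random.default_rng(seed)
    counts = np.full((4, width), (total - dominant) / 3.0)
    consensus = rng.integers(0, 4, size=width)
    counts[consensus, np.arange(width)] = dominant
    return counts


@dataclass(frozen=True)
class PromoterGenSpec:
    """Specification for a promoter-set draw with planted motif sites."""

    n_sequences: int = 20
    length: int = 2000  # promoter-window default: 2 kb around the TSS
    motif_counts: np.ndarray | None = None
    sites_per_sequence: int = 1
    strand_policy: str = "both"  # "+", "-" or "both"
    background: MarkovBackground = field(default_factory=default_promoter_background)
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1 or self.length < 1:
            raise GenerationError("n_sequences and length must be >= 1")
        if self.sites_per_sequence < 0:
            raise GenerationError("sites_per_sequence must be >= 0")
        if self.strand_policy not in ("+", "-", "both"):
            raise GenerationError(f"bad strand_policy {self.strand_policy!r}")


def synth_promoters(spec: PromoterGenSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Markov-1 background sequences with motif-sampled sites planted.

    Returns (records, truth) where records are (seq_id, sequence) pairs and
    truth has one row per planted site: seq_id, start, end, strand, word
    (word given on the motif strand).  Sites never overlap; planting
    overwrites the background so coordinates are exact.
    """
    counts = spec.motif_counts
    if counts is None and spec.sites_per_sequence > 0:
        counts = strong_motif_counts(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    width = 0 if counts is None else counts.shape[1]
    if spec.sites_per_sequence > 0 and spec.length < width:
        raise GenerationError("sequence length is shorter than the motif width")
    freqs = None
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        freqs = counts / counts.sum(axis=0, keepdims=True)  # 4 x w
    records = []
    truth_rows = []
    for s in range(spec.n_sequences):
        seq_id = f"synth_promoter_{s:03d}"
        arr = spec.background.sample(spec.length, rng)
        placed: list[tuple[int, int]] = []
        for _ in range(spec.sites_per_sequence):
            start = _place_site(rng, spec.length, width, placed)
            placed.append((start, start + width))
            word = np.array(
                [rng.choice(4, p=freqs[:, i]) for i in range(width)], dtype=np.int64
            )
            if spec.strand_policy == "both":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = spec.strand_policy
            arr[start : start + width] = word if strand == "+" else reverse_complement(word)
            truth_rows.append(
                (seq_id, start, start + width, strand, decode_sequence(word))
            )
        records.append((seq_id, decode_sequence(arr)))
    truth = pd.DataFrame(
        truth_rows, columns=["seq_id", "start", "end", "strand", "word"]
    )
    return records, truth


def _place_site(rng, length, width, placed, max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        start = int(rng.integers(0, length - width + 1))
        if all(start + width <= a or start >= b for a, b in placed):
            return start
    raise GenerationError(
        f"could not place a non-overlapping {width}-bp site after {max_tries} tries"
    )
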