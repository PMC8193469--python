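# Methods

## The logical formalism

A model is a list of components, each with a maximum activity level
(1 for Boolean, 2 for ternary) and an input flag, plus rules for every
non-input component: an ordered list of `(condition, target_level)` pairs
whose conditions are Boolean combinations of threshold literals
(`PU1:2` = "PU1 at level 2 or above", `STAT3=1` = "exactly 1"). Conditions
for distinct target levels of one component must be mutually exclusive; this
is checked exhaustively over the rule's support at load time (supports are
small, at most a handful of regulators). When no condition fires the target
is 0. Inputs have no rules and never move. A signed edge list accompanies
the rules; at load time every rule regulator is checked against it for
monotone-use/sign consistency (dually used regulators must carry a `dual`
edge).

Asynchronous updating is stepwise: a component whose target differs from its
current level moves by exactly one level toward it, one component per
transition. Stepwise multilevel transitions are the standard logical-
modelling convention; nothing in the packaged model depends on larger jumps.

## Exact analyses

**Stable states.** Depth-first constraint search over per-component domains
with generalized arc consistency: a level v stays in component i's domain
only while some assignment of i's regulators within the current domains
makes i's target equal v. Branching picks the smallest non-singleton domain;
leaves are verified with a full rule evaluation. The search is complete —
on the 55-component packaged model it needs milliseconds, and it is tested
for exact agreement with an exhaustive state scan on hundreds of seeded
random networks.

**Minimal trap spaces.** A sub-cube is closed iff every *fixed* component's
target equals its fixed value throughout the cube — a local condition
checked by enumerating the regulator assignments compatible with the cube.
The search proceeds top-down from the full cube: fix one more component,
repair closure violations by branching over the violated component's free
regulators (each regulator branches over all its levels *and* over remaining
free, so the enumeration of closed refinements is complete), and tighten
every closed cube by percolation — any component whose target is constant
throughout a cube can be fixed, because a minimal trap space inside the cube
necessarily fixes it. Sub-cubes with no proper closed refinement are
minimal; a final pairwise containment filter guards against duplicates.
Results are memoized; the engine is validated against a brute-force scan of
all `Π(max_level+2)` sub-cubes on small random networks.

**Reachability.** Best-first search (priority: summed level distance to the
goal) over the asynchronous transition graph with a memoized visited set.
Exhausting the frontier proves non-reachability; exceeding the explored-state
budget (default 500 000) returns *inconclusive* with the states-explored
count, never a negative verdict.

**Stochastic simulation.** The asynchronous transitions define a
continuous-time Markov chain: each enabled ±1 move carries the component's
`rate_up`/`rate_down` propensity (all default 1.0 per time unit; the
original analyses do not state rates, so uniform rates are the neutral
choice and are configurable per component). Trajectories are sampled with
the Gillespie algorithm, absorbed at stable states, and binned on a uniform
grid of 200 points over [0, t_max] with t_max = 50 — long enough for the
packaged model's commitment scenarios to absorb visibly. Marker-combination
curves are empirical occupancies over the ensemble; they sum to 1 at every
grid point by construction. The simulator is checked against the closed-form
single-node law and against `scipy.linalg.expm` of the explicitly
constructed generator on a three-node chain.

## The packaged moDC model

The published rule set of the source model is not distributed in machine-
readable form here, so the packaged network is a reconstruction: 55
components — inputs CSF2 and IL4; the signalling layer (CSF2 → NFKB, MAPK,
PI3K, JAK2-STAT5; IL4 → JAK1-STAT3 and JAK3-STAT6); the lncRNA LnC-DC; 18
transcription factors; and 25 marker genes (19 moDC, 2 monocyte, 4
macrophage). STAT3 and PU1 are ternary. Every edge and rule clause carries
one provenance tag:

- `literature` — canonical signalling and lineage biology (e.g. CSF2
  activates NFKB/MAPK/PI3K/JAK2/STAT5; JAK1 activates STAT3; LnC-DC raises
  STAT3 to its high level; IRF8 drives KLF4).
- `predicted` — binding-site predictions transcribed into the two
  interaction-matrix fixtures (TF × moDC-gene and TF × TF, e.g.
  PU1 → CEBPA/IRF4/IRF8 and AHR → IRF4/MAFB/PRDM1). Every matrix cell is an
  edge of the graph; rules may *refine away* a predicted edge (the edge
  remains as provenance, e.g. AHR → MAFB).
- `calibration` — the 22 modelling decisions that make the network reproduce
  the documented phenotypes. Each has an identifier and a machine ablation
  (`modc.CALIBRATION_ABLATIONS`), and the test suite demonstrates that every
  single one is load-bearing: ablating it violates at least one validation
  constraint. Examples: PI3K is inhibited by STAT6 (so PI3K is OFF in the
  moDC state); PU1 reaches level 2 only under STAT5 AND STAT6
  (co-stimulation), and level-2 PU1 both induces LnC-DC and represses MAFB;
  IRF4 requires the coincidence STAT6 ∧ NFKB ∧ AHR ∧ PU1≥1; KLF4 is
  repressed by the opposing lineage masters IRF4 and MAFB; NCOR2 is a
  required co-activator of the other 18 moDC markers; USF1/BATF3/FOXO1
  license one marker in each lineage (the mechanism behind the four-TF
  knock-out screen result).

The two interaction-matrix fixtures are *synthetic reconstructions* (the
originals are not available in machine-readable form): they satisfy every
documented constraint on them — 22 TF rows, the IRF4 row covering 13 of the 19 moDC genes,
STAT6 → TLR6/TLR8, PU1 → CD48/ITGAX, AP1 → TLR4/LY75/CD209, CREB → THBD/CD1A,
NR4A1 → CD1C, FOXO1 ≥ 6 and CEBPA ≥ 7 targets — with previously reported
cells flagged by `*`.

**Phenotype signatures** are ON/OFF/exact-level constraint sets: monocyte
(KLF4, SELL, CD14 ON), macrophage (MAFB, IRF8, CCDC151, CD206 ON), moDC
(IRF4, STAT6, CD1A, CD209 ON; PI3K = 0; STAT3 = PU1 = 2), death (both inputs
and all markers 0). OFF-requirements on the opposing lineage's markers make
the signatures pairwise unsatisfiable, which the validator re-checks on
every wild-type and mutant state. Death is labelled by signature, not by a
dedicated apoptosis node — the outcome is the label, not a mechanism.

**The validation report** asserts: one stable state per input valuation and
four in total, correctly classified; the ternary levels and MAFB/PI3K
states of the moDC attractor; strict lineage exclusivity of the marker
sets across the four states; the qualitative outcome of each of the nine
packaged mutants, encoded as machine-checkable constraints (e.g. IRF4
knock-out: at least 10 of 19 moDC markers OFF *and* at least one still ON —
"most, not all"; AHR knock-out: all 19 OFF with the macrophage state
bit-identical to wild type; JAK3 knock-out: macrophage classification under
co-stimulation); trap-space purity; and the knock-out screen producing
exactly {BATF3, FOXO1, PU1, USF1} as the TFs whose loss alters all three
committed states. In the screen, "alters a state" ignores the clamped
component itself — otherwise every expressed TF would trivially alter every
state, and the no-outgoing-edge control (EGR2) would fail.

## Motif scanning

Sites are scored as natural-log likelihood ratios: motif likelihood
(pseudocount-smoothed position frequencies, pseudocount 1 distributed by the
background's stationary composition) minus the Markov-order-1 background
likelihood of the window, with each base conditioned on its predecessor (the
base before the window where available; the reverse strand scores the
reverse complement, conditioning on the complement of the base that follows
the window). P-values are exact up to score discretization: a dynamic
programme over (position, previous base, score bin) with bin width 0.01 and
the pre-window base at stationarity yields the full null score distribution;
the discretization error of any reported p-value is below one bin's mass. A
hit must clear both thresholds — raw score ≥ 1 (the threshold is a
configurable constant in natural-log units, since the convention is not
fixed by the tools this mirrors) and p ≤ 1e-5. Windows containing non-ACGT
bases are skipped and counted. The vectorized scanner is tested for exact
hit-set equality against a naive per-window rescoring oracle, for strand
symmetry under a reverse-complement-symmetric background, and for
calibration: on ≥ 10⁷ positions of pure background the hit rate at p ≤ 1e-5
stays within 3 Poisson standard errors of 1e-5.

The interaction-matrix builder marks (TF, gene) = 1 when the TF's PSSM hits
any region mapped to the gene, with row/column margins reported. Enrichment
uses an exact hypergeometric tail (via scipy, validated against subset
enumeration) comparing a TF's observed target count to pooled counts over
(default) 100 random groups of 20 genes rescanned with identical settings —
a Fisher-style one-sided test.

## Synthetic data

Random logical networks draw a signed digraph (default max in-degree 3,
inhibitor probability 0.3, ternary fraction 0.2) and apply the default rule
convention: any activator suffices, provided all inhibitors are absent;
ternary targets reach level 2 when all activators are active. Sourceless
components are constant-0. Everything derives from one seeded generator, so
a spec+seed pair reproduces byte-identical JSON.

Promoter generation samples a Markov-1 background — default transition
matrix mildly GC-biased with CpG depletion, the gross texture of
promoter-proximal sequence — and plants motif-sampled words at non-
overlapping uniform positions by overwriting (insertions would shift
coordinates). Default length is 2 kb, matching a TSS-proximal window. The
default planted motif is high-information (15 positions, 90 % dominant
base), the regime where a stringent scanner should achieve recall ≥ 0.9; the
scanner-calibration tests instead use a moderate-information random motif
(width 12, Dirichlet(1) columns) so that the p-value threshold, not the raw
score floor, is the binding constraint and the null tail is smooth at 1e-5.

What the generators deliberately do not emulate: real promoters' positional
heterogeneity (CpG islands, TATA boxes), overlapping and clustered sites,
ChIP-seq noise, and any linkage between the network generator's topology and
real regulatory architecture. Passing tests therefore certify the *engines*
(exactness, calibration, recall in a controlled regime), not performance on
real epigenomes.

## Numerical and design choices

- Canonical state order is lexicographic over the declared component order;
  all outputs are byte-stable and every stochastic entry point requires an
  explicit seed.
- Stable-state and trap-space problem sizes: oracle tests run 200 seeded
  networks of 3–12 components (trap-space oracles on those small enough for
  the full sub-cube scan); the packaged model's analyses run in seconds.
- Commitment simulations use 1000 runs; binomial/Poisson 3-standard-error
  bands are used wherever empirical rates are compared to exact values.
- Degenerate inputs: a zero-width PSSM, all-zero count columns, empty
  sequence sets, inconsistent hypergeometric margins and malformed states
  all raise typed errors naming the offending field.

## Known limitations

- The packaged rules are a calibrated reconstruction, not a transcription of
  the original supplementary rule file; the provenance ledger separates what
  is literature, what is predicted, and what is calibration, and the
  ablation loop documents exactly which constraints pin each calibration
  choice — but other rule sets satisfying the same constraints exist.
- Trap-space search is exponential in the worst case (densely coupled
  feedback); it is exact and fast on the packaged model and on the tested
  random-network class, and it raises a budget error rather than returning
  silently incomplete results.
- The CTMC uses uniform rates; absolute time units in the commitment curves
  are therefore arbitrary, and only curve shapes and terminal probabilities
  are meaningful.
- The scanner's first window per sequence uses the background's initial
  distribution while the p-value table assumes a stationary predecessor; for
  sequences longer than a few motif widths the effect is negligible.
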