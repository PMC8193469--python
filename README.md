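# modclogic

Qualitative dynamical modelling of the *in vitro* differentiation of human
monocytes into dendritic cells (moDCs), for systems biologists working on
myeloid cell-fate decisions. Monocytes cultured with IL4 alone stay activated
monocytes, with CSF2 alone they become macrophages, and only the combination
of CSF2 and IL4 commits them to the moDC fate. `modclogic` packages a
calibrated multilevel logical model of this decision — two inputs (CSF2, IL4),
the NFKB/MAPK/PI3K/JAK-STAT signalling layer, a transcription-factor layer and
25 cell-type marker genes — together with the exact analysis machinery needed
to interrogate it, and a motif-scanning module for predicting the
transcription-factor → target edges that models of this kind are built from.

## The model class and its analyses

A logical (qualitative) model is a regulatory graph with, for each component
*i*, a rule mapping regulator levels to a target level. Most components are
Boolean (0/1); STAT3 and PU1 are ternary (0/1/2), with mutually exclusive
conditions enabling levels 1 and 2. A state **x** is *stable* when every
component sits at its target, `f(x) = x`. Asynchronous dynamics move one
component per transition by one level toward its target. The library provides:

- **Stable states** — complete enumeration by constraint search with domain
  propagation (no state-space scan; the 55-component model solves in
  milliseconds).
- **Minimal trap spaces** — all inclusion-minimal sub-cubes closed under the
  dynamics; trap spaces approximate attractors, so all-singleton minimal trap
  spaces certify the absence of cyclic attractors.
- **Reachability** — witness paths in the asynchronous state-transition graph
  (best-first, exact within an explored-state budget; running out of budget is
  reported as *inconclusive*, never as unreachable).
- **Stochastic commitment curves** — a continuous-time Markov chain over the
  logical states (per-component up/down rates, default 1/time unit), sampled
  with the Gillespie algorithm, reporting the mean probability of each ON/OFF
  combination of selected markers over time.
- **Perturbations** — knock-outs (`NAME%0`) and ectopic expression
  (`NAME%max`) clamp a component and discard its rule; a packaged panel of
  nine documented mutants and a transcription-factor knock-out screen come
  with a machine-checkable validation report.
- **Motif scanning** — PSSM log-odds scores against a Markov-order-1
  background, exact p-values by dynamic programming over (position, previous
  base, score), dual score ≥ 1 / p ≤ 1e-5 thresholds, interaction-matrix
  construction, and a hypergeometric randomization test against random gene
  groups.

Synthetic-data generators (seeded random logical networks in the same rule
class, and Markov-1 promoter sequences with planted motif sites) provide
ground truth for the oracle tests and scanner benchmarks.

## Worked example

The four wild-type attractors, one per input combination (abridged columns):

```
$ modclogic stable-states
state_index  CSF2  IL4  STAT3  IRF8  CD1A  CD14  MERTK
0            0     0    0      0     0     0     0
1            0     1    1      1     0     1     0
2            1     0    0      1     0     0     1
3            1     1    2      1     1     0     0
```

Row 0 is cell death (every component off), row 1 the activated monocyte
(KLF4, SELL, CD14 on), row 2 the macrophage (MAFB, IRF8, CCDC151, CD206 on),
and row 3 the moDC (IRF4, STAT6, CD1A, CD209 on). In the moDC state STAT3
and PU1 reach level 2 — the high PU1 level is what switches MAFB off — and
PI3K is 0, reproducing the shutdown of PI3K signalling during moDC
commitment.

Stochastic commitment from a quiescent monocyte (IRF8, FOS, AP1, CREB, ELK4
on) under co-stimulation:

```
$ modclogic simulate --csf2 1 --il4 1 --seed 7 --n-runs 1000 -o curves.tsv
```

At the end of the run the CD1A+CD209 combination (the moDC read-out among
CD1A, CD14, CD206, CD209, SELL) carries probability 1.000, while the
transient monocyte combination CD14+SELL rises to 0.130 around t = 3 before
decaying to 0.001 — cells pass through a monocyte-like intermediate before
committing.

Other entry points: `modclogic perturb --clamp NCOR2%0` (mutant stable
states, labelled `NCOR2%0 1`), `modclogic validate`
(the full calibration report), `modclogic screen` (TF knock-outs),
`modclogic scan --fasta regions.fa --pfm motifs.jaspar --pval 1e-5 --score 1`
(BED-like site predictions) and `modclogic enrich` (random-group
hypergeometric enrichment). The same functionality is available from Python
via `modclogic.load_modc_model()`, `find_stable_states`,
`find_minimal_trap_spaces`, `simulate_ctmc`, `scan_sequences`, …

## Layout

```
src/modclogic/      expressions, network, analysis, stochastic, modc,
                    motifs, synthetic, io, cli
src/modclogic/data/ packaged model JSON, interaction-matrix TSVs,
                    phenotype signatures, perturbation cases
docs/methods.md     modelling assumptions, calibration and numerics
```
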