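# Methods

`orthounmask` re-creates, as a self-contained library, the workflow used to
recognize deeply diverged orthologs of a short protein domain — the
scm3-type CENPA-chaperone module shared by HJURP, Scm3 and CAL1 — when
overall sequence identity has decayed to near-random levels, and the
comparative-evolution analyses that follow once a family has been
assembled. This note records the models, the parameters that matter, the
design choices made where the design was genuinely open, and what the
synthetic data do and do not establish.

## The detection problem and the models

The target regime is a family of proteins that share only a ~35-residue
domain (a ~25 aa recognition helix followed by a ~10 aa β-strand) embedded
in fast-evolving, length-variable, polar flanks. Pairwise identity over the
whole protein is uninformative; detection must come from position-specific
models of the domain.

**PSSM.** Per column of a seed alignment, weighted residue frequencies
(Henikoff–Henikoff position-based weights) are mixed with
BLOSUM62-conditional pseudocounts and converted to log₂ odds against the
BLOSUM62 background. The pseudocount mix is
`(α·f + β·g) / (α + β)` with `g(a) = Σ_b P(a|b) f(b)`, `α` = (distinct
residues in the column − 1) and `β` the pseudocount weight (default 5), so
a single-sequence profile reduces exactly to BLOSUM62 conditional odds —
the classic PSI-BLAST behaviour. The conditionals come from the joint
distribution implied by the BLOSUM62 scores, reconstructed from the
half-bit log-odds over the Robinson–Robinson background and balanced by
Sinkhorn scaling so that the background is exactly stationary (a column at
background frequencies scores exactly zero). Search is local
Smith–Waterman with affine gaps (defaults 11/1 in half-bit units, the
BLAST convention); the target-gap recurrence is solved by a running
maximum so the fill is vectorized.

**Profile HMM.** Columns with gap fraction ≤ 0.5 become match states;
other columns feed insert states. Match emissions use the same pseudocount
mixing; insert states emit the background (zero log-odds). Transitions
come from weighted state-path counts with additive smoothing (0.5 per
cell on the effective-count scale). The alignment mode is local: entry is
uniform over match states, and every match state carries an explicit exit
probability (0.05; the last state's residual mass), so all outgoing
transition sets sum to one and forward probabilities are well defined.
Unmatched flanking residues are emitted at background, contributing zero
log-odds — the standard free-flank convention. Forward uses log-sum-exp;
Viterbi adds a full traceback that yields the target envelope and the
residues placed in match-state coordinates (used to grow the profile).
Both are validated against exhaustive path enumeration on small models.

**E-values.** With no external database statistics available, significance
is self-contained: the model is scored against residue-shuffled decoys
(default 200) and a Gumbel tail is fitted; `E(s) = N·(1 −
exp(−exp(−λ(s−μ))))` with `N` the number of sequences searched. The
generic fit estimates both parameters by maximum likelihood. Inside the
admission loop, however, λ is fixed at ln 2 for Viterbi log₂-odds scores
and only μ is fitted (closed form). Rationale: the two-parameter MLE on a
~100–200-decoy sample is noisy, and an overestimated slope deflates tail
E-values — the one error an iterative search cannot afford, because a
chance decoy admitted at E ≈ 0.3 contaminates every later iteration. The
fixed-slope choice follows the HMMER conjecture for Viterbi score tails
and is conservative in the false-discovery direction.

**Iterative search.** Each round: build the HMM from the current profile
alignment, calibrate, score every proteome sequence, admit hits with E ≤
0.5 (the inclusion default mirrors the PSI-BLAST threshold used in the
original searches; hits up to E = 5 are reported). Admitted sequences are
realigned by Viterbi and only their match-state residues enter the
profile — admission is by domain envelope, not whole protein. Admission is
sticky: once in, a sequence stays in, which makes the admitted set weakly
monotone and convergence provable; a known-false-positive id list is
honoured (reported, never admitted). Everything is a pure function of the
seed.

**Reciprocal check.** A candidate is turned into a single-sequence PSSM
and searched against the reference orthologs pooled with the background
proteome (minus itself). It passes iff the best E-value hit is a reference
below the inclusion threshold. In the pipeline, candidates are processed
in best-E order and accepted candidates join the reference set for later
candidates: a remote ortholog's nearest validated relative is legitimately
the intermediate that unmasked it, not the original seeds.

**Domain features.** The stand-in for profile–profile (HHpred-style)
confirmation is an explicit, decomposable score with three components:
(1) the anchor — the best [KR]Y dipeptide, K at full value, R at 0.5 (the
only substitution tolerated at the lysine is conservative); (2) helix
periodicity — hydrophobic pairs ({A,V,L,I,M,F,W,C}; Y excluded because
the anchor tyrosine is scored separately) at spacings 2–4 within the 25
residues ending at the anchor; (3) strand alternation — the longest
alternating acidic (E/D) / short-hydrophobic (I/L/V) run in the 10
residues after the dipeptide. Composite = 1·anchor + 0.05·periodicity +
0.1·alternation; the weights are reporting defaults, and all three
components are exposed so thresholds can be tuned per clade (the
constraint is known to relax in some lineages).

**Structure checks.** Superposition is closed-form Kabsch (SVD, reflection
excluded); "scm3-like fold" is operationalized as region RMSD ≤ 2.0 Å
over CA *and* mean pLDDT ≥ 70 — both configuration defaults recorded in
the run manifest, not claims. Contacts use a plain 4.5 Å minimum
backbone-atom distance; without side chains this is an honest
approximation of all-atom contact determination and is labelled as such.

## Molecular evolution

**Trees.** Distance-based neighbor joining (p- or Poisson-corrected
distances; saturated corrections fall back per pair) is the built-in;
externally inferred Newick trees are accepted everywhere a topology is
needed. Congruence with a species tree is quantified by Robinson–Foulds
distance. Full ML tree search with rate heterogeneity is intentionally out
of scope.

**dN/dS.** Pairwise NG86 counts synonymous/nonsynonymous sites per codon
over non-stop single-nucleotide changes (so S + N = 3 per codon exactly),
averages multi-hit pathways over all mutational orderings through
non-stop intermediates, and applies the Jukes–Cantor correction (both
distances returned uncorrected, flagged, when the domain fails).
Whole-gene ω is the one-ratio (M0) Goldman–Yang model: F3x4 codon
frequencies from the data, reversible rate matrix scaled to one expected
substitution per codon site, likelihood by pruning (vectorized over
sites), bounded L-BFGS-B over log(ω), log(κ) and a global branch scale.
dN and dS are derived from the fitted matrix such that dN/dS = ω exactly,
with mutational-opportunity site counts from the ω = 1 matrix. Gap
handling: pairwise deletion for NG86, column-wise complete deletion for
the ML fits (counts logged).

**Site-selection test.** Null: two site classes (ω₀ ∈ [0,1] estimated,
ω = 1). Alternative: a third class with ω > 1. LRT against χ² with 2 df
(conservative at the boundary). Per-site posteriors are naive empirical
Bayes at the MLEs — not Bayes empirical Bayes — and the output labels the
method to prevent over-claiming; sites with posterior > 0.9 are flagged,
matching the conventional reporting threshold. The alternative is
optimized from multiple starts including one seeded at the null optimum,
so the LRT statistic is non-negative up to optimizer tolerance.

**Dataset filters.** Selection analyses require ≥ 8 sequences; leaves
with terminal branches > 3× the median terminal branch and rows with
ungapped length > 1.5× the median (large-insertion proxy) are dropped,
itemized. The factor 3 and the 1.5 are defaults, not facts about any
particular dataset.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (configuration, seed) and always emit
ground-truth labels alongside the data.

*Protein families* evolve an ancestral sequence down a tree under a
simple background-frequency substitution model (F81-style over 20 amino
acids) with per-site rate multipliers: anchor positions are invariant by
construction, hydrophobic-constraint positions substitute within the
hydrophobic set at reduced rate, the strand positions evolve slowly, and
flanks evolve at 4× with seeded indels (geometric lengths) confined to
the flanks — so leaf proteins are length-variable and share only the
domain, and domain coordinates remain exact. This reproduces the
*detection-relevant* features of the real regime (conserved anchored core,
diverging polar flanks, length variation) but not substitution-model
realism (no LG exchangeabilities, no rate autocorrelation), so passing
detection tests shows the pipeline recovers planted structure at realistic
divergence, not that it matches any particular empirical family.

*The stepping-stone scenario* places 4 seed sequences (clade A), one
intermediate (C) branching off the A–B path at 1.2 substitutions/site
from A, and a remote ortholog (B) at 3.2 from A (2.0 from C), plus 100
composition-matched decoys. These divergences were calibrated once during
development so that the seed profile alone misses B (E ≈ 5) while the
profile after admitting C finds it (E ≈ 10⁻⁴), and then frozen; they are
the package's standing study conditions for the detection property, not
tunable test knobs.

*Codon families* are simulated under the same GY94 machinery used for
fitting (uniform codon frequencies, per-site ω classes), which makes the
recovery tests internally consistent parameter-recovery checks rather
than robustness checks against model misspecification.

*Toy structures* are idealized backbone traces (helix rise 1.5 Å/residue,
100° twist; consecutive CA–CA ≈ 3.8 Å) with N/C/O planted along the local
chain direction — adequate for superposition, contact and confidence
logic, not for stereochemistry.

## Simulation sizes used by the tests and the acceptance script

Chosen as the package's standing study conditions: M0 recovery uses 8
taxa × 500 codons (tolerance ±20%, calibrated by a 5-replicate pilot with
maximum observed error 14%); the site-test null uses 8 taxa × 200 codons
× 20 replicates; the site-test power scenario uses a 16-taxon balanced
tree (terminal 0.4, internal 0.2) × 500 codons × 20 replicates with 20%
of sites at ω = 4. The deeper tree for the power scenario reflects a real
property of the three-class model: on shallow data its ML estimates
genuinely prefer an inflated ω₂ carried by a small class (verified to
have higher likelihood than the truth), which collapses naive
empirical-Bayes site recall; the honest remedy is more informative
alignments, not tighter optimizer bounds.

## Numerical choices

Log-space dynamic programming throughout (natural log internally, bits at
the interface); traceback ties prefer diagonal, then profile-consuming,
then target-consuming moves. Probabilities are floored at 1e-300 before
logs. NJ branch estimates below zero are clamped to zero (logged).
Optimizer bounds: ω ∈ [1e-4, 20], κ ∈ [0.1, 50], branch scale ∈
[1e-3, 100]. Coordinates and column indices are 0-based half-open
internally; all reports are 1-based inclusive. Assembly-gap coverage
requires alignments of ≥ 20 columns at ≥ 95% identity so short chance
matches never count as coverage.

## Known limitations

- E-values are calibrated against shuffled decoys, not real database
  statistics; they are comparable within a run, not across tools.
- The feature score is a sequence-pattern surrogate for profile–profile
  structure prediction; a clade that has genuinely lost a signature (as
  dipterans lost the anchor) will score low by design and needs the
  per-component outputs, not the composite.
- NEB posteriors understate uncertainty relative to BEB; flagged-site
  lists should be read with the labelled method in mind.
- The simulators share their substitution machinery with the estimators;
  recovery results are consistency checks, not external validation.
- Structure handling is backbone-only; no side-chain or all-atom logic.

## Repository shape

The package is a library-first artifact: the importable API is the
interface, `examples/` holds one short narrative script per capability,
and `scripts/acceptance.py` reproduces the headline numbers. No
command-line entry points are installed.
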