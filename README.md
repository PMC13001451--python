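# orthounmask

Detecting orthologs that sequence similarity has lost, and measuring how
they evolve once found.

Some essential proteins evolve so fast that orthologs in different phyla
share under 10% sequence identity — effectively invisible to ordinary
database search. The canonical example is the CENPA-chaperone family
(HJURP in vertebrates, Scm3 in fungi, CAL1 in flies): length-variable,
largely disordered proteins sharing only a ~35-residue domain built from
a ~25 aa recognition helix and a ~10 aa β-strand, with three sequence
signatures that outlive overall identity — a near-invariant KY dipeptide
anchor, hydrophobic residues spaced 2–4 apart along the helix, and an
acidic (E/D) / short-hydrophobic (I/L/V) alternation on the strand.

`orthounmask` is a library that implements the full unmasking workflow
for this regime and its downstream comparative analyses:

- **Position-specific search** — PSSMs (BLOSUM62-conditional
  pseudocounts, affine-gap Smith–Waterman) and profile HMMs (local
  forward/Viterbi), with self-contained E-values from a Gumbel fit to
  shuffled-decoy scores.
- **Iterative, stepping-stone search** — hits below the inclusion
  E-value (default 0.5) are realigned and folded back into the profile,
  so a moderately diverged intermediate admitted early bridges detection
  to orthologs too distant for the seed profile alone. Admission is
  sticky, deterministic under a seed, and honours an exclusion list of
  known false positives.
- **Candidate validation** — decomposable domain-feature scoring (anchor,
  helix periodicity, strand alternation), reciprocal search against
  established orthologs, and structural checks (Kabsch superposition,
  region RMSD, backbone contacts, pLDDT filtering), combined into an
  explicit per-candidate verdict.
- **Molecular evolution** — NJ trees and Robinson–Foulds congruence,
  pairwise NG86 and whole-gene M0 (Goldman–Yang) dN/dS, a
  two-vs-three-class positive-selection LRT with per-site (naive
  empirical Bayes) posteriors, dataset quality filters (≥8 sequences,
  long-branch and large-insertion exclusions), and omega contrasts
  between gene sets.
- **Synthetic data** — seeded generators for domain-bearing families,
  stepping-stone clade scenarios, decoy proteomes, codon alignments with
  known per-site ω, and toy structures, each returning ground-truth
  labels.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

`examples/02_stepping_stone_unmasking.py` runs the pipeline twice on the
calibrated three-clade scenario (4 seed sequences, intermediate C at 1.2
substitutions/site, remote ortholog B at 3.2, 100 composition-matched
decoys):

```
--- run with intermediate C (3 iterations) ---
  C          E=  4.4e-16  accepted
  B          E=  2.8e-14  accepted
  decoy_78   E=     0.62  rejected(evalue)
  decoy_14   E=      1.7  rejected(evalue)
  decoy_75   E=      3.1  rejected(evalue)
  decoy_7    E=      3.9  rejected(evalue)
--- run without C (1 iterations) ---
  decoy_14   E=      2.2  rejected(evalue)
  decoy_78   E=      2.3  rejected(evalue)
```

With C searchable, C is admitted in iteration 1, the rebuilt profile
finds B (E ≈ 3 × 10⁻¹⁴ vs E ≈ 5 from the seed profile alone), and both
pass feature and reciprocal validation; without C, B is never admitted
and nothing is accepted. The E-values are calibrated against shuffled
decoys within the run; the handful of decoys reported at E ≥ 0.6 are
rejected at the E-value gate.

The other examples cover profile construction (`01`), feature scoring and
conservation logos (`03`), structural validation (`04`), dN/dS and the
site-selection test (`05`), and the contig-gap / IP-MS micro-analyses
(`06`). Each prints the numbers it computes with a line on what they
mean.

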