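# Methods

This note documents the models, parameters and design decisions behind
`e2face`, in the spirit of a package's statistical-methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## 1. Interface-region extraction

**Model.** An NMR ensemble is treated as a set of replicate geometries of
the same two-chain complex.  For query-chain residue *r* in model *m*,
`d(r, m)` is the minimum Euclidean distance over all (residue atom,
partner-chain atom) pairs.  A residue meets the cutoff when `d(r, m) ≤ c`;
the boundary is inclusive because the criterion is stated as "within".

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| cutoff `c` | 6.0 Å | conventional heavy-atom contact shell for "near the partner"; 5.0 Å is a common stricter alternative and both are exposed via `--cutoff` |
| hydrogen policy | exclude | NMR models carry hydrogens; heavy-atom distances are the standard reading of a distance cutoff. `--include-hydrogens` flips this |
| aggregation | any-model (union) | a residue that touches the partner in *any* replicate geometry is part of the interface envelope; `all` and `count:K` are available for stricter calls |
| `max_gap` | 3 | per-model contact sets are punctate; closing ≤ 3 missing positions yields contiguous regions without bridging separate surface patches. Recorded in output metadata |

Alternate locations resolve to the first conformer; author numbering is
never rewritten; non-standard residues are carried through with a warning
and excluded from alanine scanning.  Models with mismatched residue sets
are rejected (an ensemble must describe one molecule).

## 2. Surrogate alanine scanning

Physics-based alanine-scanning ΔΔG estimators (FoldX/Rosetta-class or
commercial implementations) repack rotamers and include solvation terms.
This package deliberately uses a transparent *contact-count surrogate*
instead: truncating a side chain to CB (CB retained — the standard alanine
convention) removes its beyond-CB heavy atoms, and the score sums weights
over the inter-chain contacts those atoms made.

Contact classification is first-match-wins on each (query atom, partner
atom) pair, counted once per model:

1. salt bridge — oppositely charged groups (Lys NZ; Arg NH1/NH2/NE;
   His ND1/NE2; Asp OD1/OD2; Glu OE1/OE2), d ≤ 4.0 Å, weight 2.0
2. hydrogen bond — both atoms N or O, d ≤ 3.5 Å, weight 1.0
3. hydrophobic — both carbons, d ≤ 4.5 Å, weight 0.5
4. generic — any remaining pair, d ≤ 5.0 Å, weight 0.1

The hydrophobic+generic contribution is capped at 2.0 per residue so broad
packing cannot outrank specific polar chemistry.  Gly and Ala score 0 by
definition; Pro is truncated like any other residue.  Hot spots are
residues whose ensemble-averaged score strictly exceeds 2.5 kcal/mol.

**Calibration stance.** The weights are constants chosen so that a buried
salt-bridge-plus-hydrogen-bond residue clears the 2.5 threshold while any
purely apolar site cannot.  The surrogate's units are nominal kcal/mol;
every claim made with it is a *ranking* or a *planted-truth recovery*, and
the weight table is overridable via a config file.  Reproducing a
physics-based scorer's absolute values is an explicit non-goal.

## 3. Redundancy filtering and consensus derivation

*Pairwise identity* counts matches over columns where at least one sequence
has a residue; gap-vs-gap columns leave the denominator, gap-vs-residue is a
mismatch (the standard alignment-identity convention, stated explicitly
because several exist).

*Redundancy filter*: greedy keep-first scan in input order with the
reference forced to the front (so it is always kept); a record is removed
when its identity to any kept record strictly exceeds the threshold
(default 0.60).  Greedy keep-first is order-dependent by construction; the
removal log names the kept record that triggered each removal so the
decision is auditable.

*Consensus*: per column over the high-activity group,

* gap fraction ≥ 0.5 → wildcard;
* one residue with frequency ≥ τ_fix (0.9) → fixed;
* else take residues in decreasing frequency until their cumulative
  frequency reaches τ_class (0.9): if that prefix has ≥ 2 residues all in
  one physicochemical class → class alternative listing those residues;
* otherwise wildcard.

The class partition is a documented constant, not configuration: acidic
{D,E}, basic {K,R,H}, aromatic {F,W,Y}, aliphatic {A,I,L,M,V}, polar
{C,N,Q,S,T}, special {G,P}.  An optional negative filter demotes a
fixed/class position to wildcard when the low group matches it with
frequency > τ_low (0.5); it is off by default because the grouping already
enters through which sequences form the high set.  Ties in column counts
break by frequency then alphabetically, making derivation order-invariant.

Motif strings use `X` for fixed, `[A/B]` for class sets (alphabetical), and
lowercase `x` for wildcards; the grammar round-trips through `parse_motif`.
`classify_sequences` can test any window or only the anchored reference
window; the anchored window is interpreted in each sequence's own ungapped
coordinates, which coincides with the alignment-anchored window for the
gap-free packaged family (a caveat for heavily gapped alignments).

## 4. Weighted colocalization

The coefficient is channel-A-intensity-weighted overlap with strict
(`>`) thresholds on both channels.  The denominator defaults to
supra-threshold channel-A intensity (the convention of interactive
microscopy software "weighted colocalization coefficients"); a
whole-ROI-denominator variant is provided because the phrase "per total
signal intensity" is ambiguous.  A zero denominator returns 0 with an
explicit flag rather than NaN.  Thresholds are per-ROI inputs, mirroring
interactive per-cell thresholding; an Otsu automatic mode exists for
convenience and is labelled as such.  Per-condition summaries use the
sample SD (n−1); a single-cell condition reports SD as undefined (NaN).

## 5. Synthetic data and the packaged stand-ins

The generators produce the *statistical/geometric structure each stage
assumes*, not realistic biophysics:

* **Complexes** place CA atoms on a line at 5.0 Å spacing with idealized
  linear side chains (real atom names/elements, 1.3 Å steps, small z
  offsets at branches).  The spacing is wider than a real peptide's 3.8 Å
  so the guarantee "every non-planted residue is > 8 Å from the partner"
  is satisfiable; contact classification only sees names, elements and
  distances, so the rules apply unchanged.  Planted contacts are realized
  by placing partner residues so the designated atom pair lands inside its
  class window; per-model Gaussian jitter (default sd 0.05 Å) is re-drawn
  until all class windows and separation guarantees verify, so planted
  truth is guaranteed by construction, not on average.  A composite
  "hotspot" plant (salt bridge + two hydrogen bonds, ≥ 4 nominal kcal/mol)
  plants unambiguous hot-spot truth.
* **Families** are gap-free alignments: high-group sequences carry the
  planted motif (class positions filled round-robin so every class member
  is observed; wildcard positions filled from three different classes so
  they can never be read as conserved), low-group sequences violate the
  scrambled positions, and forced near-duplicates realize an exact
  substitution count.  Real-data features *not* emulated: gaps, indel
  structure, phylogenetic correlation, composition bias.
* **Images** plant a channel-A block of known size and cover an exact pixel
  count with channel B, so the uniform/noise-free coefficient equals the
  realized overlap fraction by arithmetic; planted fractions are realized
  to the nearest pixel.

All generators run from a single numpy PCG64 stream per call (algorithm
recorded in the truth JSON) and regenerate byte-identical files from the
same seed.

**Packaged reference stand-ins.** The deposited ensemble of the
E2–E3 complex and the curated UniProt E2 set cannot be redistributed with
the package, so `reference_complex()` and `reference_family()` construct
synthetic stand-ins that carry the documented ground truth: 10 models whose
planted contacts yield the three interface regions M1–K9, E60–P65 and
L87–Q103 under the default parameters, with R5/F63/P97 the top-ranked
ΔAffinity sites, and a labelled family whose high group yields
`[D/E]xP[F/Y]KP` at reference span 60–65 after 60% redundancy filtering.
Only the 154-residue UBE2L3 reference sequence is the real protein; every
`*_syn` record is generator-built.  Tests passing on these stand-ins
demonstrate that the *procedure* recovers planted truth under the stated
parameters — they say nothing about the deposited coordinates themselves,
which a user with database access can analyze with the same commands.

## 6. Numerical and degenerate-input conventions

* Distance boundary conditions are inclusive (`≤ cutoff`, `≤ class
  ceiling`); hot-spot and redundancy thresholds are strict (`>`).
* Empty partner chains give +infinity distances; empty residue/column
  selections and empty ROIs are errors; an empty motif renders as "".
* Region merging of an empty set returns an empty list.
* TSV/JSON outputs are fully deterministic (sorted keys, fixed float
  formats); re-running a pipeline from its manifest reproduces identical
  bytes.
* Problem sizes in tests and the acceptance script (10-model ensembles,
  154-residue chains, ≤ 25-ensemble oracle sweeps, 32×32–64×64 images) were
  chosen as the smallest sizes that exercise every code path and planted
  structure.

## 7. Known limitations

* The ΔAffinity surrogate ignores rotamer repacking, solvation,
  backbone-mediated contacts and intra-chain strain; its absolute scale is
  nominal.
* Greedy keep-first redundancy filtering does not maximize kept-set size
  (that would be a maximum-independent-set problem); it matches the common
  "remove later redundant entries" practice and is deterministic.
* The anchored motif window uses ungapped sequence coordinates (see §3).
* The toy geometry cannot probe hydrogen-inclusive distance calls beyond
  bookkeeping (generators emit no hydrogens); hydrogen handling is covered
  by parser-level tests.
* Conservation thresholds τ_fix = τ_class = 0.9 are defaults chosen to
  demand near-unanimity within the (small) high group; for larger families
  they may warrant loosening, and both are exposed.
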