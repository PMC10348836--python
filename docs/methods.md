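# Methods

## Scope and data model

The toolkit evaluates predicted multichain protein complexes.  A
`Structure` is an ordered list of chains; each chain carries the full
deposited sequence (SEQRES), the resolved residues with their atoms and
B-factors, and an explicit injective, order-preserving map from 1-based
SEQRES positions to resolved-residue positions.  Predicted models store
per-residue pLDDT (0–100) in the B-factor column; AlphaFold-style
confidence JSON supplies the predicted aligned error (PAE) matrix, an
optionally explicit pLDDT vector, and pTM/ipTM.  PAE is read as a square
matrix over the model's chain-major resolved-residue order and is allowed
to be asymmetric.

PDB is the normative structure dialect (read and written through gemmi,
including SEQRES records and the REMARK 2 resolution).  Only the first
model of a multi-model file is read; alternate locations collapse to the
highest-occupancy atom (ties to the lowest altloc letter); waters and
non-amino-acid HETATM entries are excluded; non-standard amino acids map
to 'X'.

### SEQRES↔ATOM correspondence

All cross-structure residue matching happens in SEQRES coordinates, never
by author numbering, because predicted models cover the full sequence while
experimental references resolve only part of it.  The map is built directly
from author numbering when it indexes SEQRES consistently (monotone, in
range, letters agree), otherwise by a gapped global alignment of the
resolved sequence into SEQRES that must place every resolved residue at
≥ 95 % identity.  Before any scoring, model and reference are restricted to
the residues resolved in **both** structures (per mapped chain pair,
aligning the two SEQRES strings if they differ); an empty intersection is
an error, not a silent zero.

## Reference-based scoring (DockQ)

For an interface the components are

* **fnat** — fraction of the reference's inter-chain residue contacts
  (any heavy-atom pair ≤ 5 Å) present in the model; **fnonnat** — fraction
  of model contacts absent from the reference (0 for a contactless model);
* **iRMS** — RMSD over backbone atoms (N, Cα, C, O; whichever are present
  in both structures, falling back to Cα) of the reference-defined
  interface residues (any heavy-atom pair ≤ 10 Å), after superposing those
  atoms;
* **LRMS** — RMSD of the ligand backbone after superposing the receptor
  backbone only;

combined as `DockQ = (fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3`.
The 5/10 Å cutoffs, the 1.5/8.5 Å scales and the backbone atom set are
configuration (`DockQParams`) with these conventional defaults.

Two interface protocols are provided.  *Pairwise* DockQ_ij scores one chain
pair, with the larger chain (by residues resolved in both structures; ties
lexicographic) as receptor.  *One-vs-rest* DockQ_i designates chain i as the
ligand and treats the union of all remaining chains as a single rigid
receptor — consequently a displaced chain also costs its neighbours LRMS,
which is intended: DockQ_i measures each chain's placement within the whole
assembly.  Superposition is a standard least-squares rigid fit (Kabsch via
SVD, determinant-corrected to a proper rotation); near-collinear point sets
are flagged with a warning but still fitted.

Per complex, DockQ_ij is computed for every reference chain pair in contact
and DockQ_i for every chain with inter-chain contacts.  The complex label is
ALL / SOME / NONE according to whether all, some or none of the DockQ_i
values reach the acceptability threshold 0.23 (inclusive ≥), while batch
success rates count min DockQ_i strictly above 0.23.  The asymmetry
(≥ for labels, > for success) is deliberate and kept as the two criteria are
conventionally stated.

### Chain mapping

Chain correspondence between model and reference is taken from MM-align
output when supplied (the parser returns the TM-score normalized by the
reference structure and the chain order pairing).  Otherwise chains are
matched by sequence: each model chain's candidates are the reference chains
tying its best percent identity (minimum 30 %), and if several consistent
assignments remain — homomers, ambiguous paralogs — all are enumerated
(≤ 6 chains, ≤ 720 permutations) and the one minimizing global Cα RMSD
after a single rigid superposition wins, ties breaking lexicographically.
For symmetric homomers several assignments are exactly equivalent
(RMSD 0); the lexicographic tie-break picks one deterministically, and
every downstream score is invariant to that choice.

## Reference-free confidence

Both scores share the four-parameter sigmoid
`score(X) = L/(1+exp(−k(X−x₀))) + b` (evaluated via tanh for stability) and
an 8 Å Cβ–Cβ (Cα for glycine) contact definition, exposed as configuration.

* **pDockQ** (per chain pair): X = ⟨pLDDT⟩_int · ln N_int, where N_int
  counts contact pairs (unique-residue counting is available as an option)
  and ⟨pLDDT⟩_int averages over the unique residues on both sides.  No
  coefficients are hardcoded for pDockQ: they must be supplied or fitted.
  A per-chain summary (`pdockq_chain`) takes the maximum over the chain's
  pairwise interfaces.
* **pDockQ2** (per chain): over all inter-chain contact pairs of chain i,
  each pair's PAE is the mean of its two directed matrix entries (making
  the score invariant to PAE orientation), and
  X_i = ⟨1/(1+(PAE/d₀)²)⟩ · ⟨pLDDT⟩_int with d₀ = 10 Å.  Defaults:
  L = 1.31, x₀ = 84.733, k = 0.075, b = 0.005.  Averaging over all
  interface residue pairs instead of contact pairs is exposed as an option,
  as is ligand-side-only pLDDT.  Chains without inter-chain contacts are
  reported absent rather than given the floor score b, mirroring the
  benchmark practice of excluding contactless chains.

pDockQ2 is monotone non-increasing under uniform PAE inflation and bounded
in (b, L+b); both properties are tested.

### Sigmoid calibration

`fit_sigmoid` is nonlinear least squares (scipy `curve_fit`) over
(L, x₀, k, b), started at (1, median x, 0.05, 0) with bounds L ∈ (0, 2],
k ∈ (0, 1], b ∈ [0, 0.5], x₀ within the data range, plus up to three seeded
jittered restarts; it requires ≥ 20 points, responses in [0, 1] and a
non-constant response.  Note the fitted curve's ceiling L + b may exceed 1
(the published coefficients give 1.315): response data clamped to [0, 1]
therefore saturates above X ≈ 104, and calibration data should sample the
unsaturated range (recovery tests use X ∈ [0, 100], where noiseless
recovery is exact to < 1e-4 per parameter).

## Benchmark curation

Curation operates on precomputed tables: an all-vs-all MM-score similarity
TSV, a per-chain percent-identity TSV, and an entry metadata TSV.  External
aligners are never executed; absent edges stand for pairs the upstream
prefilter skipped.

**HCS clustering.**  Edges below the MM-score threshold (default 0.6,
roughly "same fold" at whole-complex level) are removed; each connected
component is recursively split along a global minimum edge cut until every
component G has edge connectivity strictly greater than |G|/2; singletons
and two-node components count as clusters, and split-off singletons are
kept as such (no adoption step).  Determinism: the cut is anchored at the
lexicographically smallest node s; among sorted sinks t the first achieving
the global minimum s–t cut value is used, and of all minimum s–t cuts the
unique one with minimal source side (residual reachability from s) is
taken — uniqueness follows from cut submodularity, so the result does not
depend on max-flow internals.  An exhaustive-enumeration implementation of
the same rule serves as the test oracle on small graphs.

**Representative selection.**  Best (lowest Å) resolution wins; ties go to
the smallest total SEQRES-minus-ATOM length difference, then to the
lexicographically smallest id; entries without a resolution lose to any
entry with one.

**Identity filtering.**  An entry is removed iff any of its chains has any
table hit at ≥ 30 % identity (inclusive); a ledger records the triggering
hit per removed entry.  The filter is monotone in the threshold.

## Synthetic study conditions

The generator builds idealized poly-helical chains — Cα on a standard
α-helical trace (2.3 Å radius, 100°/residue, 1.5 Å rise) with an explicit
radial Cβ at 1.5 Å, default 30 residues, sequences drawn from the 19
non-glycine amino acids (so both contact schemes work without side chains;
glycine handling is tested separately) — arranged with 10 Å axis spacing
either on a line (translated copies; non-adjacent chains share no contacts)
or a ring (C_n-symmetric rotated copies, so homomeric rings have identical
interfaces).  Adjacent chains share ≥ 38 Cβ contacts at 8 Å.

Models are per-chain rigid perturbations: a rotation about a seeded random
axis and/or a translation along a seeded random direction, or an in-place
*flip* (180° about the radial axis plus a 1.5 Å approach) that preserves a
large interface while destroying every native contact — the
"confident-but-wrong" regime in which interface size and pLDDT alone
overrate a model.  A chain counts as misdocked when flipped, translated
≥ 10 Å or rotated ≥ 90°; the labels are verified against DockQ_i < 0.23 in
the tests.

Synthetic confidence mirrors how failure manifests in real predictions:
pLDDT is high everywhere (90 minus half-normal noise, sd 2 by default),
deliberately uninformative about docking correctness, while PAE carries the
signal — entries within a chain and across correctly placed chain pairs are
drawn around 2 Å (sd 1), pairs involving a misdocked chain around 25 Å, all
truncated to AlphaFold's [0, 31.75] Å range with a zero diagonal.  These
defaults are fixed once as the study conditions for all tests.

What the generator does **not** emulate: real side-chain packing and
physical interface chemistry, partially resolved references with long
disordered regions, correlated PAE structure within domains, pLDDT
degradation near wrong interfaces, and alignment-depth effects.  Passing
tests therefore demonstrate the correctness of the scoring machinery and
the qualitative PAE-blindness contrast between pDockQ and pDockQ2, not
quantitative performance on experimental benchmarks.

## Numerical choices and limitations

* Contacts are extracted with a KD-tree and reported once per residue pair
  with the minimal qualifying distance; an exhaustive all-pairs oracle
  checks exact equality in the tests.
* Superposition RMSDs agree with an independent quaternion-method (Horn)
  oracle to 1e-9.
* Acceptance thresholds: DockQ 0.23, MM-score agreement 0.75, clustering
  MM-score 0.6, identity 30 % — all configurable, defaults printed by
  `mqa config`.
* Problem sizes in the test suite and acceptance script (20 self-evaluated
  complexes, 50 contact fixtures, 20 exhaustively checked graphs, 100+100
  labelled chains, 50 dimers) were chosen to exercise every code path at
  desk scale; all randomness is integer-seeded and platform-independent.
* Degenerate inputs fail loudly: empty native contact sets, zero common
  residues, dimension-mismatched PAE, constant calibration responses and
  sub-minimal point sets all raise typed errors rather than returning
  sentinel scores.
* mmCIF files are accepted through the same gemmi-backed reader, but PDB
  is the tested, normative dialect.  Nucleic-acid chains, biological
  assembly generation and CAPRI multi-class ranking are out of scope.
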