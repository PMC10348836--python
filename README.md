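# mqa — multi-interface quality assessment for predicted protein complexes

Structure-prediction pipelines such as AlphaFold-Multimer now produce
multichain complex models routinely, but a single global score hides the
question practitioners actually ask: *which interfaces of this complex can I
trust?*  `mqa` is a toolkit for answering that question, both when a
reference structure exists and when it does not:

* **Reference-based scoring.**  DockQ — the CAPRI-style combination of the
  fraction of native contacts (fnat), interface RMSD (iRMS) and ligand RMSD
  (LRMS),

  `DockQ = ( fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²) ) / 3`

  — computed per chain pair (DockQ_ij) and per chain against the union of
  all remaining chains treated as one rigid receptor (DockQ_i).  A complex
  is labelled ALL / SOME / NONE according to how many of its one-vs-rest
  interfaces reach the acceptability threshold (DockQ ≥ 0.23), and batch
  success rates use min DockQ_i > 0.23.

* **Reference-free confidence.**  pDockQ scores a chain-pair interface from
  its size and mean interface pLDDT, X = ⟨pLDDT⟩·ln N_int, through a sigmoid
  L/(1+exp(−k(X−x₀)))+b.  pDockQ2 scores each chain i over *all* its
  interfaces and additionally folds in the predicted aligned error,
  X_i = ⟨1/(1+(PAE/d₀)²)⟩·⟨pLDDT⟩ with d₀ = 10 Å, so a large, confidently
  packed but wrongly docked interface — invisible to pDockQ — is caught.
  The published pDockQ2 coefficients (L = 1.31, x₀ = 84.733, k = 0.075,
  b = 0.005) ship as defaults, and `fit_sigmoid` recalibrates them against
  observed DockQ values.

* **Benchmark curation.**  Highly-connected-subgraph (HCS) clustering of an
  all-vs-all MM-score table (threshold 0.6), representative selection by
  resolution then SEQRES/ATOM difference, and ≥30 % sequence-identity
  filtering against a reference set — all operating on precomputed TSV
  tables from MM-align / MMseqs2.

* **Synthetic test bed.**  A seeded generator of idealized multichain
  complexes, rigid-body-perturbed models of known per-chain quality, and
  quality-consistent pLDDT/PAE, so the full pipeline runs and is tested
  without downloading anything.

Model and reference residues are matched by SEQRES position and scoring is
restricted to residues resolved in both structures; chain correspondence
comes from MM-align output (parsed, not executed) or an internal
sequence-identity + permutation-search mapper.

## Worked example

Generate a synthetic trimer whose chain B is misdocked in place (flipped:
still packed against its neighbours, but every native contact destroyed),
then score it with and without the reference:

```sh
mqa synth --seed 11 --n-chains 3 --misdock 1 --out-dir demo
mqa evaluate demo/model.pdb demo/native.pdb
mqa score demo/model.pdb --pae demo/confidence.json
```

`mqa evaluate` reports (abridged):

```json
{
  "min_dockq_i": 0.0558, "max_dockq_i": 0.5007, "label": "SOME",
  "dockq_i": {
    "A": {"dockq": 0.5007, "fnat": 0.5625, "lrms": 2.33},
    "B": {"dockq": 0.0558, "fnat": 0.0625, "lrms": 26.21},
    "C": {"dockq": 0.4813, "fnat": 0.5000, "lrms": 2.26}
  }
}
```

Chain B keeps only 6 % of its native contacts and its DockQ_i of 0.056 is
far below the 0.23 acceptability line, while A and C remain acceptable —
hence the SOME label.  The reference-free scores agree without ever seeing
the native structure:

```json
{
  "per_chain": {"A": 0.0553, "B": 0.0107, "C": 0.0484},
  "min_pdockq2": 0.0107
}
```

pDockQ2 puts chain B at 0.011: its interface PAE is high, so the
d₀-scaled PAE term collapses X_i even though the interface is large and its
pLDDT is high (the regime in which size-and-pLDDT scores like pDockQ
over-predict).  A and C score low here too because their interfaces with
the misdocked B inflate their PAE term — pDockQ2 is a per-chain summary
over *all* of a chain's interfaces.

The same machinery is available as a library:

```python
from mqa import synthetic, evaluate_complex, pdockq2_complex

native, model, conf, truth = synthetic.generate_case(seed=11, n_chains=3, misdock=[1])
ev = evaluate_complex(model, native)           # DockQ_ij, DockQ_i, label
scores = pdockq2_complex(model, conf)          # per-chain pDockQ2 + min
```

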