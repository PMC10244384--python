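# tcravidity

Sequence- and structure-based inference of **TCR structural avidity** — the
strength of monomeric pMHC–TCR binding, measured as the dissociation
half-life *T*<sub>1/2</sub> (seconds) of fluorescent pMHC monomers off live
T cells.

High-avidity T cell clones preferentially infiltrate and control tumors, but
measuring avidity clone-by-clone is slow and needs the cognate antigen. This
package implements an in-silico route for immunologists and computational
biologists who have CDR3β sequences (and, optionally, upstream structural
models): cluster receptors by biophysicochemical similarity, predict each
clonotype's avidity class from solvent-exposed CDR3β residues, and test
whether predicted high-avidity clonotypes are enriched among
tumor-infiltrating lymphocytes.

## What it computes

**1. Biophysicochemical CDR3β clustering.** Every CDR3β is decomposed into
sliding 4-mer subunits after trimming the first 4 and last 3 residues (which
rarely contact the peptide). Each 4-mer is encoded by the five Atchley
factors per position (hydrophobicity, secondary structure, size/mass, codon
degeneracy, charge), compared by Manhattan distance normalised to [0, 1],
and two TCRs are scored by the *minimum* over all 4-mer pairs. UPGMA on the
resulting matrix gives an ultrametric dendrogram; a clade search locates the
**hotspot** most enriched in intermediate/high-avidity TCRs
(*T*<sub>1/2</sub> > 10 s), judged against a label-permutation null that
re-runs the search on every permutation.

**2. Contact-count half-life regression.** For complexes with modeled
structures, a simplification of the binding free energy:

    T½(s) = K + γ·n_apolar + δ·n_polar

fitted by ordinary least squares on measured half-lives
(`ContactHalfLifeModel.fit()` → `ContactHalfLifeResults`).

**3. Exposure-gated logistic avidity classifier.** The probability that a
TCR is high avidity (*T*<sub>1/2</sub> > 60 s):

    p = 1 / (1 + exp(−(b₀ + W₁·R + W₂·N + W₃·D + W₄·G + W₅·I + W₆·L + W₇·F)))

where each indicator is 1 iff that amino acid occurs in the CDR3β at a
position with relative solvent exposure **strictly above 30 %** (buried
residues cannot touch the peptide). The residue set itself comes from an
exhaustive search over all 5–8-residue subsets of the 20 amino acids
(257,754 subsets per encoding; presence / exposed-presence / frequency
encodings), ranked by linear-model R² and refit as logistic models ranked by
ROC AUC. Three cross-validation schemes (random leave-20 %-out, stratified
leave-20 %-out, leave-one-epitope-out) quantify robustness.

**4. Repertoire %HA enrichment.** Classifier labels are tracked into bulk
blood and tumor β-chain repertoires by exact CDR3β match (single-read
clonotypes dropped). Matched clonotypes split into *n* infiltrating (found
in tumor) and *m* non-infiltrating (blood only); the statistic
%HA<sub>Inf</sub> − %HA<sub>No</sub> is judged against a relabeling null in
which each clonotype is independently redrawn high with probability
F/(n+m), F being the pooled high-avidity count.

A synthetic-data module generates panels, exposure profiles, contact tables
and paired repertoires with *planted* composition→avidity coupling, exposure
masks and linear contact structure, so every stage has a parameter-recovery
test without external data.

## Worked example

```python
>>> import tcravidity as tv
>>> tv.extract_kmers("CASSLAPGATNEKLFF")
['LAPG', 'APGA', 'PGAT', 'GATN', 'ATNE', 'TNEK']
>>> tv.predict_halflife(-62.89, 2.647, 8.747, n_apolar=30, n_polar=5)
60.254999999999995
```

A 16-residue CDR3β yields 16 − 10 = 6 four-mer subunits; a complex with 30
apolar and 5 polar modeled contacts is predicted to sit right at the 60 s
high-avidity boundary.

Refit the contact model on a synthetic 10-complex table generated at those
coefficients, then train the classifier on a synthetic 48-TCR panel
(11 high / 37 low) with a planted exposure-gated signal:

```python
>>> import numpy as np
>>> from tcravidity.classifier import build_feature_matrix
>>> from tcravidity.simulate import generate_feature_coupled_panel
>>> records = tv.generate_contacts(tv.ContactSpec(n_complexes=10, seed=1))
>>> print(tv.ContactHalfLifeModel.from_records(records).fit().summary())
Contact-count half-life model (OLS)
  n complexes:  10
  K     (s):            -62.8900  (SE 0.0000)
  gamma (s/apolar ct):   2.6470  (SE 0.0000)
  delta (s/polar ct):    8.7470  (SE 0.0000)
  R^2:          1.0000
  residual SD:  0.0000 s

>>> panel, exposures = generate_feature_coupled_panel(
...     tv.PanelSpec(n_tcrs=48, high_fraction=11/48, seed=1))
>>> labels = [int(c.is_high_avidity) for c in panel]
>>> fdef = tv.FeatureDefinition()   # {R,N,D,G,I,L,F}, exposed_presence, >30%
>>> X = build_feature_matrix([c.cdr3b for c in panel], fdef, exposures)
>>> res = tv.AvidityLogisticModel(X, np.array(labels, float), fdef).fit()
>>> tv.evaluate_classifier(res, X, labels)   # doctest: +SKIP
{'auc': 0.962, 'sensitivity': 0.636, 'specificity': 1.0, 'accuracy': 0.917,
 'tp': 7, 'fp': 0, 'tn': 37, 'fn': 4}
```

The noiseless table returns the generating coefficients exactly (R² = 1);
the classifier separates the planted classes with AUC 0.96 at the 0.5 call
threshold (here 0 false positives, 4 false negatives out of 48).

The same stages are scriptable from the shell:

```bash
tcravidity simulate --n-tcrs 48 --seed 1 --outdir demo
tcravidity distance demo/panel.tsv --out demo/dm.tsv
tcravidity cluster demo/dm.tsv demo/panel.tsv
tcravidity fit-contacts demo/contacts.tsv
tcravidity train demo/panel.tsv demo/exposure.tsv
tcravidity run-all --seed 1 --outdir demo_run   # everything + manifest.json
```

## Layout

| Module | Contents |
| --- | --- |
| `tcravidity.atchley` | Atchley table, 4-mer extraction/encoding, TCR distances |
| `tcravidity.clustering` | UPGMA, newick export, hotspot search, permutation null |
| `tcravidity.contacts` | `ContactHalfLifeModel` / `Results` (OLS on contact counts) |
| `tcravidity.classifier` | features, `AvidityLogisticModel` / `Results`, search, CV, composition enrichment |
| `tcravidity.repertoire` | label tracking, %HA relabeling test |
| `tcravidity.simulate` | synthetic panels, exposures, contacts, repertoires |
| `tcravidity.io`, `tcravidity.pipeline`, `tcravidity.cli` | TSV readers/writers, `RunConfig`/`run_pipeline`, `tcravidity` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and the
scope of what the synthetic benchmarks do and do not establish.
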