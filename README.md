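# admeprofiler

`admeprofiler` is a Python library and command-line tool for profiling small
molecules in early drug discovery. From nothing but a SMILES string it
computes the physicochemical, pharmacokinetic and medicinal-chemistry
readouts a discovery chemist wants on one page: descriptor panel,
multi-method lipophilicity with a consensus, three aqueous-solubility
models, skin permeation, BOILED-Egg absorption/brain-penetration flags, six
rule-based drug-likeness filters, the Abbott bioavailability score, a
six-axis bioavailability radar, PAINS/Brenk structural alerts, a
leadlikeness check and a fragment-frequency synthetic-accessibility (SA)
score. It also ships the SVM model-building pipeline used to train binary
substrate/inhibitor classifiers (e.g. P-glycoprotein, CYP isoforms) from
labelled descriptor data.

## The core methods

* **TPSA** — Ertl fragmental polar surface area, with sulfur and phosphorus
  treated as polar: TPSA = Σᵢ cᵢ over polar-atom environments (Å²).
* **WLOGP / MR** — Wildman–Crippen purely atomistic log *P*o/w and molar
  refractivity: per-atom contributions summed over 68 atom classes.
* **MLOGP** — Moriguchi topological log *P*: a 13-parameter regression,
  log P = 1.244·CX⁰·⁶ − 1.017·NO⁰·⁹ + … − 1.041.
* **Consensus log P** — arithmetic mean of every available predictor
  (WLOGP, MLOGP, a table-driven fragmental method, plus external-value
  slots for predictors such as XLOGP3 that need outside software).
* **log S** — ESOL (linear in log P, MW, rotatable bonds, aromatic
  proportion), the Ali TPSA model, and a 16-fragment system modulated by
  √MW; classes on the scale
  insoluble < −10 < poorly < −6 < moderately < −4 < soluble < −2 < very < 0 < highly.
* **log Kp** — Potts–Guy skin permeability,
  log Kp(cm/h) = −2.74 + 0.71·log P − 0.0061·MW, reported in cm/s.
* **BOILED-Egg** — position in the (TPSA, WLOGP) plane against two
  ellipses: the white (high passive gastrointestinal absorption) and the
  yolk (high blood–brain-barrier permeation); regions overlap.
* **SA score** — every 1–7-bond linear path of a molecule is hashed onto a
  1024-bit fingerprint; a library of purchasable molecules gives each bit a
  contribution ln(count/max count); the molecule's mean bit contribution,
  corrected by size and complexity penalties (chiral centres, spiro atoms,
  bridged rings, macrocycles), is mapped onto 1 (very easy) … 10 (very
  hard to synthesize).
* **SVM pipeline** — descriptor rejection (< 20 % non-zero values,
  coefficient of variation < 3 %, pairwise |r| > 0.9 resolved by F-score),
  class balancing by Ward clustering with cluster-centre selection,
  training-set normalization, RBF-kernel SVM with coarse-then-refined
  log₂ grid search maximizing 10-fold cross-validated accuracy, and
  external evaluation (ACC, AUC, sensitivity, specificity).

## Worked example

```python
>>> from admeprofiler import ADMEProfiler
>>> profiler = ADMEProfiler().fit()
>>> p = profiler.profile_one("CC(=O)Oc1ccccc1C(=O)O")
>>> round(p.descriptors.tpsa, 2), round(p.lipophilicity.wlogp, 2)
(63.6, 1.31)
>>> round(p.lipophilicity.consensus, 2), p.solubility["esol"].class_label
(0.39, 'very soluble')
>>> p.filters["Lipinski"].passed, p.bioavailability_score
(True, 0.56)
>>> p.pk.hia, p.pk.bbb, round(p.sa.normalized, 1)
(True, True, 4.7)
```

Aspirin has a polar surface area of 63.6 Å² and an atomistic log P of 1.31;
it passes the rule-of-five (bioavailability score 0.56, the default class),
is predicted well absorbed and brain-penetrant (inside both egg regions)
and is synthetically easy-ish (SA 4.7 against the small packaged reference
library — scores shift with the library used, see `docs/methods.md`).

From the shell:

```bash
admeprofiler profile -i molecules.smi -o report.csv
admeprofiler egg -o egg.csv "CCO" "c1ccccc1"
admeprofiler sa-table -i library.smi -o sa_table.json
admeprofiler svm train -i train.csv --label-col label -o model.json
```

`profile` writes one CSV row per input molecule (a failing SMILES yields an
error row, never an aborted batch); `egg` writes the BOILED-Egg plot table.

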