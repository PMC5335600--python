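# Methods

This note documents the models behind `admeprofiler`, the choices made
where a design was genuinely open, the synthetic-data conditions the test
suite runs under, and known limitations.

## Input standardization

A molecule enters as a SMILES string (one per line, optionally followed by
a one-token name; unnamed molecules become `Molecule_<k>`). Standardization
(RDKit underneath): parse and sanitize; keep the largest covalent fragment
(counter-ions and minor fragments dropped); record the **as-input formal
net charge**; neutralize simple protonation states (carboxylate → acid,
protonated amine → amine) while leaving permanent charges (quaternary
ammonium, charge-separated groups such as nitro) untouched; kekulize.
Charge-dependent scores — the bioavailability score in particular — use
the as-input charge, since ionization is what those models were
parameterized on; every property is otherwise computed on the neutralized
form, and reports carry a flag when neutralization occurred.

## Descriptors

The panel holds ~60 features: composition counts, ring/stereo analysis,
TPSA (Ertl fragmental sum with polar S and P included), Wildman–Crippen
molar refractivity, rotatable bonds (non-ring single bonds between
non-terminal heavy atoms, amide C–N excluded — the definition the Veber
rule assumes), and two H-bond count flavours: Lipinski-style (all N+O,
all NH+OH) for the rule-of-five, and stricter pharmacophoric counts for
the Muegge filter. Fraction Csp3 is defined as 0 for carbon-free input
(flagged). A multi-fragment input measured before fragment stripping is
additive in TPSA, MR and WLOGP; the tests exercise this.

## Path fingerprint (1024 bits)

Linear paths of 1–7 bonds over heavy atoms (hydrogens implicit) are
enumerated exhaustively; each path is encoded as its sequence of
(atomic number, formal charge) atoms and bond orders (aromatic = 1.5,
doubled to stay integral), the lexicographically smaller of the two
traversal directions is taken, and the byte string is hashed with 32-bit
FNV-1a modulo 1024. The dialect identifier `path1-7/fnv1a32/1024` is
stored in every frequency table and checked at scoring time; any
self-consistent dialect works because table builder and scorer share it.
The enumeration is validated against a brute-force simple-path enumerator
on all small fixture molecules.

## Lipophilicity

* **WLOGP** — Wildman–Crippen atomistic sum (RDKit's implementation of the
  published 68-class system). Validated against hand-typed contribution
  sums over the published class values on a 20-molecule fixture panel.
* **MLOGP** — the Moriguchi 13-parameter regression, implemented here from
  the published equation. The narrative parameters were operationalized as
  follows: *PRX* adds 2 per N/O pair one bond apart and 1 per pair two
  bonds apart; *HB* (intramolecular H-bond dummy) fires when a donor and an
  acceptor heteroatom lie exactly four bonds apart across an aromatic
  path; *POL* counts polar substituent attachment points on aromatic
  carbons (first atom a heteroatom/halogen, or a carbonyl-like carbon);
  *AMP* is 1 for α-amino acids and 0.5 for aminobenzoic/pyridinecarboxylic
  acids; *ALK* marks pure hydrocarbons with at most one double bond and no
  aromatics; *RNG* marks any ring system that is not a carboaromatic ring;
  *QN* is 1 for quaternary N and 0.5 for N-oxides; *NCS* counts
  isothiocyanate (1.0) / thiocyanate (0.5); *BLM* marks β-lactams. These
  readings follow the published parameter descriptions; molecules
  dominated by the heuristic parameters (HB, POL, AMP) carry the largest
  uncertainty.
* **Fragmental log P** — a table-driven hybrid model (SMARTS-keyed
  fragment counts plus descriptor terms). The packaged default table is a
  **synthetic stand-in** with directionally sensible coefficients, clearly
  labelled as such; supply a coefficient file to reproduce a specific
  published fragmental system.
* **External slots** — predictors requiring outside software (XLOGP3) or
  solvation physics (GB/SA-based methods) are read from a user-supplied
  file (`name,predictor,value`). The **consensus** is the arithmetic mean
  of whatever predictors are available, with the contributor count
  reported.
* **Lipophilicity slot** — downstream models specified on XLOGP3 (ESOL,
  Ali, Muegge, leadlikeness, radar, skin Kp) take a pluggable value: the
  external XLOGP3 number when supplied, else WLOGP, with the substitution
  recorded in the report.

## Solubility and pharmacokinetics

ESOL: log S = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP, with AP
the aromatic fraction of heavy atoms. Ali (TPSA model): log S = 0.4654 −
1.0364·logP − 0.0210·TPSA; the coefficients are exposed as module
constants and should be replaced if a different fit of that model family
is wanted. Fragmental: log S = intercept + (Σ cᵢ·nᵢ)/√MW over a
16-fragment SMARTS table (packaged default synthetic, as above). The class
scale assigns boundary values to the more soluble side (the published
scale uses strict inequalities in both directions, leaving boundaries
ambiguous). Conversions: mol/l = 10^logS, mg/ml = 10^logS·MW.

Skin permeation: Potts–Guy, log Kp(cm/h) = −2.74 + 0.71·logP − 0.0061·MW,
printed in cm/s by subtracting log₁₀3600.

BOILED-Egg: the white (absorption) and yolk (brain penetration) regions
are ellipses in the (TPSA, WLOGP) plane loaded from configuration; points
outside the plot range (default TPSA 0–200 Å², WLOGP −4…8) are flagged and
classified negative for both readouts. The packaged geometry is an
**axis-aligned approximation reconstructed from the published region
extents** (white: TPSA ≤ 142, WLOGP −2.3…6.8; yolk: TPSA ≤ 79, WLOGP
0.4…6.0) — the original best-fit ellipse coefficients are not public.
Classifications near the region boundaries are therefore approximate;
replace the config with fitted coefficients for exact reproduction.

## Drug-likeness

Thresholds are configuration data (`data/config_defaults.yaml`), not code:
Lipinski (MW ≤ 500, MLOGP ≤ 4.15, HBD ≤ 5, HBA ≤ 10; "pass" tolerates one
violation per the rule-of-five convention, with the count always
reported), Ghose (MW 160–480, WLOGP −0.4…5.6, MR 40–130, 20–70 atoms
including H; closed intervals), Veber (RB ≤ 10, TPSA ≤ 140), Egan
(WLOGP ≤ 5.88, TPSA ≤ 131.6), Muegge (MW 200–600, logP −2…5, TPSA ≤ 150,
rings ≤ 7, C > 4, heteroatoms > 1, RB ≤ 15, HBA ≤ 10, HBD ≤ 5) and
leadlikeness (MW 250–350, logP ≤ 3.5, RB ≤ 7). Every breached sub-rule is
emitted as a violation string; filters are pure functions of the panel.

The bioavailability score maps anions (as-input charge < 0) by TPSA
(≤ 75 → 0.85, ≤ 150 → 0.56, else 0.11) and everything else by rule-of-five
compliance (pass → 0.56, fail → 0.17). The default-class constant is 0.56
here, configurable to the 0.55 printed in the original publication.

Radar axes and compliant ranges: lipophilicity (slot value) −0.7…6.0,
size 150–500 g/mol, polarity 20–130 Å², solubility (ESOL log S) ≥ −6,
saturation (fraction Csp3) ≥ 0.25, flexibility ≤ 9 rotatable bonds. The
lipophilicity ceiling is configurable (a 5.0 variant circulates); 6.0 is
the default. Drug-like = all six axes in range.

## Structural alerts and SA score

PAINS and Brenk catalogs default to RDKit's curated built-in collections
(480 and 105 patterns respectively); a file loader accepts any
`SMARTS<TAB>description` catalog, validates each pattern (naming the
offending line) and optionally enforces an expected count. Screening
reports each matched pattern once, in deterministic order.

The SA frequency table counts, per bit, the number of library molecules
setting that bit; contributions are ln(count/max count), so the most
common fragment contributes 0 and rarer fragments are increasingly
negative; bits never observed carry a floor of ln(0.5/max count)
(pseudo-count 0.5, configurable). The raw score is the mean contribution
over the molecule's set bits minus non-negative penalties: size
(n^1.005 − n over heavy atoms), log₁₀(1+count) for chiral centres
(potential centres included), spiro atoms and bridgehead atoms, and
log₁₀2 for any macrocycle (ring of more than 8 atoms) — the published
penalty coefficients of the fragment-based accessibility literature. The
affine map onto [1, 10] is calibrated per table from the raw-score range
of its own build library (stored with the table; clipped at both ends; a
degenerate single-molecule library anchors its member at the easy end).
Scores are therefore comparable only against the same table. The packaged
default table is built over a 125-molecule mini-library of common drugs
and reagents — adequate for testing monotonicity, range and determinism,
*not* a substitute for a production table built over millions of
purchasable compounds (`admeprofiler sa-table` builds one from any SMILES
file).

## SVM pipeline

Descriptor rejection: non-zero fraction < 20 %, coefficient of variation
(sample SD/|mean|; infinite when the mean is 0 with positive SD, so such
columns are kept; zero-SD columns rejected) < 3 %; among survivors
correlated with |r| > 0.9, the feature with the higher class-separation
F-score — (m₊−m)² + (m₋−m)² over the summed within-class variances — is
kept, greedily in descending F-score order. The procedure is idempotent
and column-order invariant up to relabeling.

Class balancing: the larger class is clustered to the target size with
Ward linkage (scipy's nearest-neighbour-chain implementation — the
reciprocal-nearest-neighbour algorithm) on 1 − Tanimoto distances over the
package's path fingerprints (the metric is a parameter); each cluster
contributes its centre, the member with the smallest summed dissimilarity,
ties to the lowest input index.

Training: features are normalized to zero mean/unit variance with
parameters stored from the training set and reused verbatim on test data.
(C, γ) are scanned over log₂ grids — C: 2⁻⁵…2¹⁵, γ: 2⁻¹⁵…2³, step 2² —
maximizing mean 10-fold stratified cross-validated accuracy, then refined
around the winner at half the log step; ties prefer smaller C then smaller
γ. AUC_CV is reported at the winning parameters, so it inherits a mild
selection ("winner's curse") bias — visible as single-run permuted-label
AUCs occasionally above 0.6 while the mean over seeds sits at chance.
External evaluation reports ACC, ROC-AUC from decision values, sensitivity
and specificity. Models persist as JSON (normalization, kernel expansion);
a loaded model evaluates the RBF expansion directly.

### Synthetic data conditions

The generator draws two unit-variance Gaussian classes (default 50
features, 10 informative) whose means differ by `effect_size` SDs on the
informative features, plus class-prototype fingerprints with 10 % bit
noise; everything is reproducible from the seed. The test suite runs at
n = 100 + 100 per dataset with effect size 3 SD (separable) and 0 SD /
permuted labels (null), 10 seeds in the acceptance property. These
conditions probe the pipeline's mechanics — filtering, leakage-free
normalization, grid search, evaluation — not chemistry: real
substrate/inhibitor sets are smaller-effect, correlated and imbalanced,
so passing here does not certify real-data accuracy. The pipeline accepts
user-supplied descriptor CSVs for real training.

## Numerical and degenerate-input choices

Boundary log S values take the more soluble class; filter interval bounds
are inclusive; Lipinski-style thresholds are strict (a value exactly at
4.15 complies). A single-atom molecule sets no fingerprint bits and gets
fragment term 0. Cross-validation folds shrink to the minority-class size
when needed (never below 2). Descriptor columns with zero variance get
unit scale in normalization to avoid division by zero.

## Known limitations

* Predictors needing closed-source software or solvation free-energy
  physics are external-value slots, not reimplementations; with none
  supplied the consensus averages the native predictors and downstream
  models run on WLOGP (flagged).
* The packaged fragmental log P / log S coefficient tables are synthetic
  stand-ins; their absolute values are not meaningful, only the table
  mechanics are.
* The egg geometry is an approximate reconstruction (above).
* The MLOGP heuristic parameters (HB, POL, AMP) follow narrative
  descriptions and may differ from the original implementation on ornate
  molecules.
* The curated PAINS collection used by default has 480 patterns; the
  481-entry variant that circulated with an older filtering-tool
  distribution is not redistributable here.
* P-gp/CYP classifiers are not shipped trained: the published training
  collections are external; the pipeline trains them when those sets are
  supplied.
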