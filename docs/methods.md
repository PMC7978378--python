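# Methods

This note records the scientific and numerical choices behind `adascreen`:
what each component computes, the defaults and why, what the synthetic data
emulate, and where the design was genuinely open.

## Molecule handling

Molecules are used *as drawn*: no protonation-state or tautomer enumeration
is attempted. Multi-fragment inputs are reduced to the largest fragment (by
heavy-atom count, ties by molecular weight) before any fingerprinting or
property computation — a deterministic surrogate for full structure
preparation. Unparseable library entries are returned as structured parse
failures with line numbers, never silently dropped.

Properties follow the simple counting conventions used by decoy-selection
tools: HBD = number of N-H and O-H hydrogens, HBA = number of N and O
atoms, logP by the Crippen atom-contribution method, MW as the standard
average-mass sum. Lipinski's rule is applied with inclusive boundaries
(MW = 500.0 passes) and the canonical one-violation allowance.

Dataset splitting is stratified per class with largest-remainder
apportionment (remainder ties resolved toward the earlier set, so
train >= test >= validation on ties) and a mandatory seed. At the study's
population of 310 actives + 405 inactives and a 7:2:1 ratio this yields
sets of 501/143/71.

## Fingerprints and similarity

Three schemes: binary ECFP4 (radius-2 circular, hashed to 2048 bits — the
community default at library scale), a count-folded Morgan variant of the
same radius, and 166-bit MACCS keys. Tanimoto on binary vectors is
|A&B|/|A|B|; on count vectors the min/max generalization. Tc of two empty
vectors is *defined* as 0 (avoids 0/0 and keeps novelty conservative), and
Tc values are never compared across schemes.

Diversity clustering is Butina sphere exclusion: neighbors at Tc >=
threshold, centroids picked by descending unassigned-neighbor count with
input-order tie-breaks. The threshold is a free parameter — no default is
claimed to reproduce any particular historical cluster count, because the
original clustering tool and cutoff are unpublished.

Novelty of a candidate hit is the per-scheme maximum Tc against a reference
set of known actives; values below ~0.4 in ECFP-type schemes indicate a
genuinely new chemotype.

## The two classifiers

Both are trained with Adam on softmax cross-entropy with L2 weight decay
(biases not decayed), all randomness (init, shuffling, dropout) derived
from the config seed, no early stopping. Initialization is uniform scaled
by 1/sqrt(fan-in).

**Dense network (DNN).** Input: binary ECFP4 bits. Defaults mirror the
selected optimum of the original campaign: three ReLU hidden layers of
3000/2000/1000 units, dropout 0.2, L2 1e-4, learning rate 1e-3, 500
epochs, batch size 250.

**Neural graph fingerprint (NFP).** Atom features are the standard set:
element one-hot over {C,N,O,S,F,Cl,Br,I,P,other}, degree one-hot (0-5),
total-H-count one-hot (0-4), aromatic flag (22 dims). At each of
`conv_layers` radii (default 5) every atom's vector is replaced by
ReLU(W * (self + sum of neighbors)); at every radius (including radius 0)
a per-atom softmax projection writes into a real-valued fingerprint of
`fp_length`, summed over atoms and radii — so the fingerprint is invariant
to atom input order by construction. The fingerprint feeds one ReLU hidden
layer (`hidden_width`) and a two-class softmax. `fp_length` (2048) and
`hidden_width` (100) are not pinned by the source campaign; the defaults
match the ECFP comparison length and the scale of the reference NFP
implementation.

Both networks run on a small in-package reverse-mode autodiff engine
(topological-sort backprop over matmul/add/ReLU/row-softmax/cross-entropy
nodes). Analytic gradients are checked against central finite differences
(worst relative error < 1e-4 on multi-layer graph networks) in the suite.

The batch-size grid search trains one model per size (the study grid is
50..300 in steps of 50), tabulates SE/SP/Q+/Q-/MCC/AUC on the test
partition, and selects by MCC with AUC tie-break. Library filtering keeps
compounds with active-class probability strictly above the threshold
(default 0.5 — "passed the filter" needs a concrete rule); the dual gate is
the set intersection of the two filters. Class weighting is not applied
(310:405 is near-balanced).

## Screening metrics

Confusion-matrix metrics use exact integer/rational arithmetic with a
single floating square root for MCC; a metric with a zero denominator is
reported as undefined (None), never as 0. Display rounding is 3 dp for the
classifier metrics and 2 dp for ranked-list metrics, matching the
conventions of the reporting tables.

Ranked lists may carry *unranked actives* (actives the screen failed to
score, e.g. pharmacophore non-matchers). The default places them after
every ranked entry — the pessimistic choice — for AUC, BEDROC and AUAC
alike; BEDROC also offers an `exclude` mode since reporting practice
varies. Score ties are broken against the actives (an active never ranks
above an equally scored inactive), making tied metrics lower bounds.

EF uses a ceil top bin: ceil(fraction*N) entries. With the 42-active /
913-decoy validation universe this reproduces the printed EF1% values
exactly: a fully active 10-entry bin gives (10/10)/(42/955) = 22.74, six
actives give 13.64.

BEDROC uses the full Truchon-Bayly normalization (RIE scaled by the
hyperbolic min/max terms), not the RIE-ratio shortcut; the suite verifies
it against a direct Boltzmann-summation min/max oracle to 1e-9. At the
published alpha = 160.9 essentially all weight lies in the top ~2% of
ranks, so 35-of-42 actives at ranks 1-35 saturates the metric (0.9981,
printing as 1).

AUAC is the trapezoidal area under cumulative-fraction-of-actives vs
fraction screened over all N ranks.

Cheng-Prusoff is applied with the radioligand conditions of the two
binding assays as shipped constants: [3H]DPCPX 2.5 nM at Kd 2.1 nM (A1)
and [3H]ZM241385 0.5 nM at Kd 2.06 nM (A2A). `p_transform` converts nM to
the pKi/pIC50 scale.

## Pharmacophore matching

Hypothesis *generation* is out of scope (the original common-feature
perception runs in closed-source software and the published hypothesis
geometry is unavailable); hypotheses are supplied by the user as YAML
sites {type, x, y, z, tolerance} plus `min_match`.

Feature perception uses the SMARTS listed in
`adascreen.pharmacophore.DEFAULT_FEATURE_SMARTS` (auditable in source):
acceptors are N/O with an available lone pair excluding amide-type and
anilinic nitrogens, donors are N-H/O-H heavy atoms, aromatic rings are
placed at ring centroids, hydrophobes at centroids of connected
aliphatic-carbon patches with no heteroatom attachment. An atom may carry
several types (hydroxyl O is both A and D).

Matching searches site subsets from the full hypothesis down to
`min_match`, and within each subset all injective type-consistent feature
assignments (hypotheses have <= 6 sites, so exhaustive search is cheap and
exact). Each candidate is scored by Kabsch least-squares rigid
superposition of feature positions onto site positions; it is accepted only
if every matched pair lies within its site's tolerance after alignment
(1e-9 slack absorbs floating-point noise at exact-boundary constructions).
The accepted match with the most sites wins, ties by lowest rmsd.
Default site tolerance: 2.0 A, the conventional matching scale; exposed
per site.

Conformers: when a record has no 3D coordinates, up to 10 seeded ETKDG
conformers are embedded (with hydrogens, reported on heavy atoms); a
molecule passes the screen if *any* conformer matches. Rigid-motion
invariance and tolerance/min-match monotonicity are property-tested.

## Decoy selection

Greedy scan in pool order under the six criteria: Tc(candidate, every
active) < 0.75; |dHBA| <= 2, |dHBD| <= 1, |dMW| <= 25 Da, |dlogP| <= 1
against at least one active (per-active matching, as in the originating
tool; matching against the pooled property range is noted as an
alternative); Tc(candidate, every accepted decoy) < 0.9. Tc thresholds are
strict inequalities (literal reading of the criteria), property windows
inclusive. ECFP4/2048 is used for all decoy Tc values, keeping the toolkit
internally consistent even though the originating tool's fingerprint
differs. Default quota 36 per active (the historical 913 decoys for 42
actives is not an integer per-active target; the quota is configurable).
Every examined candidate is logged with its accepting active or the first
failing criterion, and an independent `verify_decoys` re-check of all six
criteria runs as a test invariant.

## The funnel

Stages only remove compounds; the report records (input, output) counts
per stage and the per-stage scores of final candidates, and re-running
with identical inputs is byte-identical. "Top X%" retention uses ceil.
The docking stage is replaced by external-score ingestion by design —
commercial docking stacks cannot be a dependency — and the final
visual-inspection cut is modeled as an explicit include-list file so the
manual step stays auditable.

## Synthetic study fixtures

`generate_synthetic_library` emulates the *shape* of the training problem —
a structurally coherent active class against a diverse inactive background —
with two families that are separable by construction: positives are a
xanthine-like fused bicyclic scaffold (the caffeine chemotype, the
classical nonselective adenosine antagonist) with N-alkyl decorations;
backgrounds are random acyclic amine/ether chains with no aromatic system.
It does **not** emulate the hard parts of real screening data: activity
cliffs, shared scaffolds across classes, assay noise, or class imbalance at
library scale. Passing the recovery tests therefore demonstrates that the
training/evaluation machinery is correct, not that the models would attain
any particular accuracy on real bioactivity data.

Problem sizes used by the suite (the package's own choice of test scale):
100 + 100 molecules, 70/30 split, DNN with 64/32 hidden units and 40
epochs on 512-bit fingerprints, NFP with 2 radii, 64-length fingerprint,
32 hidden units and 60 epochs. Both reach SE, SP and MCC of 1.0 on the
held-out 30% at these sizes; the label-shuffled control (5 seeds, 15
epochs) centers on AUC 0.45-0.55. The full-width defaults
(3000/2000/1000, 500 epochs) remain the package defaults for real use.

`generate_ranked_fixture` builds deterministic ranked lists ("top",
"bottom", "interleaved", or explicit ranks; surplus actives become the
unranked tail) and feeds the metric validation directly.

## Known limitations

- No protonation/tautomer/stereoisomer enumeration; results on drawn
  structures can differ from prepared-structure pipelines.
- Pharmacophore matching is rigid per conformer; torsional flexibility is
  only captured through the conformer ensemble.
- The NFP implementation is CPU numpy; it is sized for datasets of
  hundreds-to-thousands of molecules, not millions (the dense model scales
  much further since fingerprinting dominates).
- The published library-scale funnel attrition counts and assay potencies
  depend on proprietary libraries, commercial docking software and wet-lab
  data, and are not reproducible from this package alone; the metric-level
  quantities recomputed by `scripts/acceptance.py` are.
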