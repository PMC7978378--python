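# adascreen

Multistage ligand-based virtual screening for **dual adenosine A1/A2A
receptor antagonists**, a nondopaminergic strategy against Parkinson's
disease. The package implements the full in-silico funnel used to mine a
large vendor library for dual antagonists:

1. **Dual deep-learning gate** — a dense neural network over binary ECFP4
   fingerprints and a neural-graph-fingerprint (NFP) network over molecule
   graphs are trained on actives (Ki < 40 nM at both receptors) vs
   inactives (Ki > 1000 nM); only compounds predicted active by *both*
   models survive.
2. **Pharmacophore gate** — perceived acceptor/donor/aromatic/hydrophobe
   features are partially matched (e.g. 4 of 5 sites) against a 3D
   hypothesis under per-site tolerance radii via exhaustive type-consistent
   assignment plus least-squares rigid superposition.
3. **External-score ranking** — docking or any other external score table
   is ingested as CSV and survivors are kept by sequential top-fraction
   cuts; scoring itself is deliberately pluggable, never computed here.

Around the funnel the package provides property-matched decoy selection
(the six DecoyFinder-style criteria), Butina diversity clustering,
maximum-Tanimoto novelty assessment, and the statistics used to validate
every stage.

## The statistics at the core

For a 2x2 screen outcome with counts TP, FP, TN, FN:

    SE = TP/(TP+FN)          SP = TN/(TN+FP)
    Q+ = TP/(TP+FP)          Q- = TN/(TN+FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

For a score-descending ranked list of N compounds containing n actives at
ranks r_i:

    EF(x)   = (hits in top ceil(x*N) / ceil(x*N)) / (n/N)
    RIE     = mean_i exp(-a*r_i/N) / E[random]
    BEDROC  = RIE-based Truchon-Bayly min/max normalization onto [0,1]
    AUAC    = trapezoidal area under cumulative-actives vs fraction-screened
    AUC     = tie-corrected pairwise concordance P(score_a > score_i)

Assay math: the Cheng-Prusoff conversion `Ki = IC50 / (1 + [C*]/Kd*)` for
competition binding against a radioligand at concentration [C*] with
dissociation constant Kd*.

## Worked example

```python
>>> import adascreen as ada
>>> from adascreen.screenmetrics import ConfusionCounts, EnrichmentParams

>>> # the best dense model's test outcome: 36 actives, 81 inactives
>>> ms = ada.confusion_metrics(ConfusionCounts(tp=36, fp=6, tn=75, fn=0))
>>> round(ms.se, 3), round(ms.sp, 3), round(ms.q_plus, 3), round(ms.mcc, 3)
(1.0, 0.926, 0.857, 0.891)

>>> # pharmacophore validation: 42 actives + 913 decoys, all of the
>>> # ceil(1% of 955) = 10 top-ranked entries active
>>> ranked = ada.generate_ranked_fixture(955, 42, "top")
>>> round(ada.enrichment_factor(ranked, EnrichmentParams(fraction=0.01)), 2)
22.74

>>> # 35 actives ranked 1-35, 7 missed by the model (bottom ranks)
>>> ranked = ada.generate_ranked_fixture(955, 42, list(range(1, 36)))
>>> round(ada.bedroc(ranked, EnrichmentParams(alpha=160.9)), 4)
0.9981

>>> # competition IC50 -> Ki under the A1 radioligand conditions
>>> round(ada.cheng_prusoff(2.190476, ada.DPCPX), 3)
1.0
```

An MCC of 0.891 with SE = 1 means the classifier recalls every test active
while keeping false positives low; an EF1% of 22.74 means the top 1% of the
ranked screen is 22.7-fold enriched in actives over random picking, and the
BEDROC value of ~1 at alpha = 160.9 confirms that almost all recognition
weight sits in the earliest ranks.

A shell session mirrors the same calls:

```console
$ adascreen metrics confusion --tp 36 --fp 6 --tn 75 --fn 0
SE      1.0
SP      0.926
Q_PLUS  0.857
Q_MINUS 1.0
MCC     0.891
```

## Layout

| module | role |
| --- | --- |
| `chemstore` | SMILES/CSV/SDF ingestion, properties, Lipinski, stratified splits |
| `fingerprints` | ECFP4/Morgan/MACCS, Tanimoto, Butina clustering, novelty, molecule graphs |
| `neuralmodels` | autodiff engine, DNN + NFP classifiers, batch-size grid search, filtering |
| `screenmetrics` | SE/SP/Q+/Q-/MCC, ROC AUC, EF/BEDROC/AUAC, Cheng-Prusoff |
| `pharmacophore` | feature perception, rigid superposition, partial matching, screening |
| `decoygen` | six-criteria property-matched decoy selection with audit trail |
| `cascade` | funnel orchestration, reporting, synthetic fixture generators |
| `cli` | `adascreen` console entry point |

See `docs/methods.md` for the modelling choices, defaults and limitations.
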