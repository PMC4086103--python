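# fragspec

Tandem-MS (ESI-MS/MS) toolkit for small molecules: predict
[M+H]+ / [M−H]− product-ion spectra of a neutral structure at three
collision energies (10/20/40 V), annotate observed peaks with enumerated
fragment structures, and rank candidate structures against observed
spectra. Aimed at metabolomics practitioners who need in-silico spectra
and peak explanations for compounds that have no library spectrum.

## The model

A molecule's fragmentation possibilities are enumerated by systematic
bond disconnection into a directed acyclic graph: nodes are candidate
fragment ions, edges are cleavage events labelled with their neutral
loss. Fragmentation is then modelled as a d-step Markov chain on this
graph. From fragment *i* the ion stays intact with score θ_b or takes
cleavage *e* with score θ_f · Φ(e), where Φ(e) is a fixed-length cleavage
feature vector (bond order, ring opening, H rearrangement, common
neutral-loss flags, loss mass, heteroatom content); move probabilities
are the softmax of these scores. The marginal occupancy after d steps
gives the predicted peak intensities:

    P(move = e | i) = exp(θ_f·Φ(e)) / (exp(θ_b) + Σ_e' exp(θ_f·Φ(e')))
    intensity(m/z) ∝ Σ_{nodes at m/z} P(F_d = node)

One such model is kept per collision energy. Parameters are learned from
(molecule, spectrum) pairs by expectation-maximization: observed peak
intensity is soft-assigned to mass-matched graph nodes, expected
transition counts come from a forward–backward pass, and the M-step is
an L2-penalized softmax regression. Identification scores candidates by
the Jaccard overlap between predicted and observed peak sets, averaged
over the provided collision energies.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Train on a synthetic benchmark and identify a "query" molecule:

```sh
fragspec simulate --n 10 --seed 3 --out-dir bench
fragspec train --library bench/library.txt --spectra-dir bench/spectra \
               --iterations 10 --out-dir models
fragspec identify --spectra bench/spectra/M000.txt \
                  --candidates bench/library.txt \
                  --model-dir models --top-k 3
```

which prints (`M000` is the true molecule for that query):

```
rank	ref_id	score	smiles
1	M000	0.8480	CCC1COOC1
2	M005	0.2497	CN1CCON1
3	M008	0.2473	COC(CO)C(C)O
```

rank is the candidate's position after sorting by score; score is the
Jaccard peak-set overlap in [0, 1] averaged over the three collision
energies — 0.85 means the predicted and observed peak lists agree almost
everywhere, and the decoys explain far fewer peaks.

Predicting a spectrum directly from the library API:

```python
from fragspec import parse_structure, predict, reference_models, POSITIVE

spectra = predict(parse_structure("CCO"), POSITIVE, reference_models())
for peak in spectra["medium"].peaks:
    print(f"{peak.mz:.5f} {peak.intensity:.2f}")
```

```
13.00728 43.09
15.02293 100.00
17.00219 65.56
17.03858 93.74
19.01784 78.92
29.03858 68.59
```

Each line is m/z (Da) and relative intensity (base peak = 100) of the
medium-energy (20 V) prediction for protonated ethanol fragments.

The statsmodels-style surface wraps training with diagnostics:

```python
from fragspec import SingleEnergyModel
res = SingleEnergyModel(dataset, energy_level="medium").fit(maxiter=15)
print(res.summary())      # per-feature weights with standard errors
res.predict(molecule)     # Spectrum under the fitted parameters
```

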