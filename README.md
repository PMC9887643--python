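# attnmpi

Prediction of metabolite–protein interactions (MPIs) from protein sequence
and compound features, using self-attention over residues and multi-head
cross-attention pooling keyed on the metabolite — together with the data
machinery such models need to be evaluated honestly: duplicate collapsing,
similarity clustering for leakage control, cold-start (double-blind) splits,
frequency-respecting negative sampling, and randomized baselines.

It is aimed at computational biologists who want to train and stress-test
sequence-based interaction classifiers, and at method developers who need a
reference implementation of the double-blind evaluation protocol.

## The model

A pair (metabolite *i*, protein *j*) is scored in four stages:

1. **Protein encoder.** The sequence is tokenized (BEGIN + residues + END,
   right-padded to *N* tokens), embedded with per-residue feature vectors
   (one-hot identity channels plus standardized property channels), summed
   with sinusoidal positional encodings, and passed through a stack of
   transformer encoder layers, each wrapped in a learnable residual
   connection `x + g·layer(x)` with the scalar gate `g` initialized at 0.
   The stack can be pretrained by masked-residue prediction.
2. **Compound encoder.** The processed feature vector (global
   physico-chemical properties + decoded 2D substructure fingerprint) passes
   through batch normalization and linear layers with rectifier activations
   to an embedding `X_met ∈ R^128`.
3. **Cross-attention pooling.** For each of *M* heads, two-layer perceptrons
   project both sides into a common attention space of size *S*:
   `H_met = φ_met(X_met)`, `H_prot,k = φ_prot(X_prot,k)`; similarities
   `θ_k = ⟨H_met, H_prot,k⟩ / √N` become attention weights
   `α = softmax(θ)` over all *N* positions (padding included), the sequence
   is pooled as `Z = Σ_k α_k H_prot,k`, and a per-head linear map takes *Z*
   to size *S*//*M* before concatenation.
4. **Prediction head.** `[pooled ‖ X_met]` passes through fully-connected
   residual blocks and a final linear map; a sigmoid yields
   `P(interaction) ∈ (0, 1)`.

Simplified variants replace the transformer with the identity (`NT`) and/or
attention pooling with average pooling (`AvP`); a logistic-regression
variant serves as a sanity baseline. Training uses Adam on binary
cross-entropy with a batch-size/weight-decay schedule that doubles the batch
at fixed epochs while halving the decay (constant product — the large-batch
analogue of learning-rate decay).

Evaluation routes every pair into train / protein-blind / metabolite-blind /
double-blind folds by single-linkage clustering of entities (Euclidean
distance on residue-composition vectors for proteins, on fingerprints for
metabolites, with distance thresholds linear in sequence length 7→29 and in
compound mass 1.2→5), so near-duplicates never straddle folds.

## Worked example

```bash
attnmpi synth  --seed 7 --out toy/
attnmpi split  --pairs toy/interactions.tsv --proteins toy/proteins.fasta \
               --metabolites toy/metabolites.tsv --seed 7 --out toy/folds/
attnmpi train  --pairs toy/folds/ --proteins toy/proteins.fasta \
               --metabolites toy/metabolites.tsv --seed 7 --out toy/run/
attnmpi evaluate --model toy/run/last.npz --pairs toy/folds/ \
               --proteins toy/proteins.fasta --metabolites toy/metabolites.tsv \
               --seed 7 --out toy/report/
```

or in Python:

```python
from attnmpi import synthdata, pipeline

cohort = synthdata.generate_cohort(synthdata.SynthConfig(seed=1))
result = pipeline.run_training(cohort.positives(), cohort.sequences,
                               cohort.met_frame, seed=1)
for name, report in result.reports.items():
    print(f"{name:18s} AUCROC={report.aucroc:.3f} acc={report.accuracy:.3f}")
print("rule ceiling:", synthdata.bayes_auc(cohort.config))
```

which (with these seeds, on one CPU in a few minutes) prints

```
train              AUCROC=1.000 acc=0.994
protein_blind      AUCROC=0.914 acc=0.879
metabolite_blind   AUCROC=0.915 acc=0.876
double_blind       AUCROC=0.921 acc=0.847
rule ceiling: 0.948
```

The double-blind row is the headline: neither the metabolite, nor the
protein, nor any near-duplicate cluster member was seen in training, so the
score measures how much of the planted interaction rule the model actually
learned. The ceiling is the Monte-Carlo AUC of the generating rule itself
under the same balanced resampled-negative evaluation; a well-trained model
approaches it, and a feature-randomized baseline (`attnmpi corrupt`) drops
to chance.

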