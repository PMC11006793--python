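# smorfkit

Tools for building species-specific **smORF coding-potential models** and
scanning genomes for novel small open reading frames.

Small ORFs (≤ 101 codons including the stop) encode microproteins that
standard gene annotation largely misses, and their short length defeats
conservation-based coding-potential methods. `smorfkit` trains a classifier
that separates translated smORFs (mRNA coding sequences) from non-coding ORFs
(the maximal ORFs of ncRNA transcripts) using only sequence-intrinsic
features, then applies it genome-wide — including ORFs initiated at
near-cognate, non-ATG start codons — to emit a filtered smORF database
(FASTA + BED6 + TSV).

## Model

Each training example is an ORF prefixed by its three upstream nucleotides.
Feature classes:

- **Basic**: ORF length in codons, 1-mer and 2-mer composition.
- **TIS (Kozak-context) bias**: for each site *i* ∈ {−3, −2, −1, 4, 5, 6}
  around the start codon, the log-likelihood ratio
  ln *p*⁺(*x*ᵢ)/*p*⁻(*x*ᵢ) of the observed nucleotide under the positive vs
  negative site-probability tables — a 6-dim vector.
- **In-frame features**: the hexamer score
  Σ ln *f*⁺(*h*)/*f*⁻(*h*) over in-frame 6-mers; the codon usage bias
  (1/*n*) Σ ln *p*⁺(*C*ᵢ)/*p*⁻(*C*ᵢ), where *p*(*C*) is a codon's count over
  its amino-acid class count; and the Fickett position parameter
  max(*b*₁,*b*₂,*b*₃)/(min(*b*₁,*b*₂,*b*₃)+1) per nucleotide.
- **Discontinuous k-mers**: 3-/4-mers and g-gap / g-bigap patterns.

The complete vector is 1169-dim; feature ablation and mRMR-IFS (mutual
information quotient ranking + incremental selection) reduce it to the
shipped 33- and 32-dim schemas. The default classifier is a random forest
(`max_features='sqrt'`); evaluation reports SN, SP, PRE, ACC, F1S, HM
(harmonic mean of SN and SP), MCC and trapezoid ROC/PR AUC. For genome
scanning, each start codon carries its own score cutoff, calibrated to a
target precision — near-cognate starts must clear a stricter bar, and the
weakest (AAG/AGG) are excluded outright.

## Worked example

Train on synthetic data (biased codon usage + Kozak-like context in the
positives) and evaluate on a held-out split:

```python
from smorfkit import (SynthConfig, generate_training_sets, assemble_datasets,
                      Dataset, train_model, predict_scores, compute_metrics,
                      confusion, curve_and_auc, get_schema)

cfg = SynthConfig(n_pos=300, n_neg=300, seed=7)
pos, neg = generate_training_sets(cfg)
train, test = assemble_datasets(pos, neg, seed=7)
tp = Dataset([r for r in train if r.label == "positive"])
tn = Dataset([r for r in train if r.label == "negative"])
model = train_model(tp, tn, get_schema("final32"), method="RF", seed=7)

scores = predict_scores(model, test)
y = [r.label for r in test]
rep = compute_metrics(*confusion(scores, y, 0.5))
_, auc = curve_and_auc(scores, y, "roc")
print(f"ACC {rep.ACC:.3f}  MCC {rep.MCC:.3f}  SN {rep.SN:.3f}  "
      f"SP {rep.SP:.3f}  ROC AUC {auc:.3f}")
```

This prints

```
ACC 0.980  MCC 0.960  SN 0.990  SP 0.970  ROC AUC 0.998
```

i.e. at the default 0.5 cutoff the model classifies 98% of held-out ORFs
correctly, recovers 99% of true smORFs (SN) while rejecting 97% of
non-coding ORFs (SP), and ranks positives above negatives almost perfectly
(AUC). The synthetic generator plants strong biases, so these numbers
reflect the construction, not performance on real transcripts.

The same pipeline from the shell:

```bash
smorfkit synth training --n-pos 300 --n-neg 300 --seed 7 --out work/train
smorfkit train --pos-train work/train.pos.fa --neg-train work/train.neg.fa \
               --schema final32 --seed 7 --out work/model.bundle
smorfkit synth genome --contig-len 6000 --plant ATG:30:+ --plant CTG:20:- \
               --seed 8 --out work/toy
smorfkit scan --genome work/toy.fa --gff work/toy.gff3 \
              --model work/model.bundle --out work/db
```

`work/db.{fa,bed,tsv}` then hold the scored, cutoff-filtered smORF database
for the toy genome. Other subcommands: `prep` (assemble train/test splits
from ORF FASTAs with redundancy removal), `featurize`, `evaluate`, `select`
(`--mode ablation|mrmr-ifs`).

## Acceptance script

`scripts/acceptance.py` exercises the whole pipeline from scratch —
synthetic data generation, train/test assembly, model training, held-out
evaluation, precision-targeted cutoff calibration, genome scan and database
emission — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the modelling choices, synthetic-data assumptions
and known limitations.
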