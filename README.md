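# phoskit

A machine-learning toolkit for phosphorylation-site prediction. It covers the
whole workflow: collecting PTM-annotated protein data from several formats,
extracting window-based features, training a bagged classifier suited to
highly unbalanced site data, calibrating decision thresholds to estimated
specificity, and predicting sites in new sequences at a chosen stringency.

## What it does

- **Data model** (`phoskit.core`): proteins with 1-based PTM annotations and
  per-residue score tracks; annotation merging across sources with status
  reconciliation; site statistics; non-redundant labeled dataset construction
  (exact window-peptide deduplication, positive-wins conflict resolution,
  configurable negative-site policy).
- **I/O** (`phoskit.io`): FASTA (Biopython-backed), a native PTM XML dialect
  that round-trips annotations and tracks losslessly, UniProt XML conversion
  (`modified residue` features, with evidence-status filtering), and
  Phospho.ELM-style tab-delimited reports.
- **Features** (`phoskit.features`): KNN scores (fraction of a site's k most
  similar labeled reference windows that are positive, under BLOSUM62
  window similarity, for several k-fractions), mean window disorder (built-in
  propensity heuristic or any externally supplied track), and amino-acid
  frequencies.
- **Classifiers** (`phoskit.classifiers`): a linear SVM and an AdaBoost stump
  learner behind a common contract, combined by a bootstrap-aggregating
  ensemble that trains each round on a balanced subsample and averages
  decision values.
- **Train/predict** (`phoskit.pipeline`): end-to-end training with 5-fold
  cross-validated pooling of held-out negative scores into an empirical
  specificity calibration curve; prediction at any stringency in (0, 1);
  filtering; portable single-file model archives (zip of JSON + TSV).
- **Synthetic data** (`phoskit.synth`): a deterministic phosphoproteome
  generator with planted motif and disorder signal, so the full pipeline is
  testable without downloads.

## CLI

```bash
# generate synthetic training data (PTM XML with disorder tracks)
phoskit synth --seed 7 --out data.xml

# convert real data instead: UniProt XML -> PTM XML, keeping chosen statuses
phoskit convert --from uniprot-xml --to musite-xml --status experimental,probable in.xml data.xml
phoskit merge data.xml other.xml --out merged.xml
phoskit stats data.xml --ptm Phosphorylation

# add built-in disorder tracks for proteins that lack them
phoskit disorder data.xml --out data_dis.xml

# train and predict
phoskit train --xml data_dis.xml --residues S,T --out model.mdl --seed 1
phoskit predict --model model.mdl --fasta query.fasta --stringency 0.95 --out out.tsv

# model management
phoskit model info model.mdl
phoskit model rename model.mdl "my model"
phoskit model comment model.mdl "trained on merged 2026 data"
```

Prediction output is a TSV with columns
`accession  position  residue  score  est_specificity  passes`.

## Model archive format

A model file is a zip containing `model.json` (name, comments, residue types,
window half-width, KNN configuration, serialized ensemble, calibration
scores, format version) and `reference.tsv` (the labeled reference windows
needed to compute KNN features at predict time, one `peptide<TAB>label` row
per window). Archives are byte-deterministic for identical inputs and seeds.
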