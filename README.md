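# eegselect

Multi-objective EEG channel selection for epileptic-seizure
classification. Per-channel EEG epochs are decomposed into sub-bands —
empirical mode decomposition (EMD, keeping the two IMFs closest to the
original signal) or a 4-level biorthogonal-2.2 discrete wavelet
transform — and four features are extracted per sub-band (instantaneous
energy, Teager energy, Higuchi and Petrosian fractal dimensions: 8
features per channel for EMD, 20 for DWT). Channel subsets are then
searched with NSGA-II or NSGA-III (implemented from scratch), or with a
greedy backward-elimination baseline, to jointly maximize 10-fold
cross-validated accuracy over a four-classifier portfolio (SVM, k-NN,
random forest, Gaussian naive Bayes) and minimize the number of
channels.

A synthetic two-class epoch generator (pink-noise background plus a
spike-wave rhythm confined to known channels) makes the whole pipeline
testable without any recorded data. Real recordings can be supplied as
EDF files with the 22-channel bipolar scalp montage (the CHB-MIT
convention: 256 Hz, down-sampled to 128 Hz, balanced 6-s epochs cut
around seizure-interval annotations given as a `start_s,end_s` CSV).

## Layout

| module | contents |
| --- | --- |
| `eegselect.synth` | synthetic epoch generator (`SynthConfig`, `generate_epochs`) |
| `eegselect.edfio` | minimal EDF reader/writer, montage constant, down-sampling, balanced epoching |
| `eegselect.decompose` | EMD sifting + IMF selection; bior2.2 wavelet filter bank |
| `eegselect.features` | energy / fractal-dimension features, `FeatureTable` |
| `eegselect.evaluate` | stratified-CV classifier portfolio (`evaluate_subset`) |
| `eegselect.moo` | NSGA-II / NSGA-III, Pareto archive, backward elimination |
| `eegselect.pipeline`, `eegselect.cli` | end-to-end runs, CSV reports, `eegselect` CLI |

## CLI

Each stage is independently invocable (`eegselect <cmd> --help` for all
flags):

```sh
# generate a synthetic epoch set (EDF directory)
eegselect synth --channels 8 --informative 1,4 --n-per-class 40 --snr 3 \
    --out runs/epochs --seed 1

# feature table as CSV
eegselect features --channels 8 --informative 1 --method dwt --out runs/features.csv

# channel selection end-to-end (writes pareto.csv, history.csv,
# classifier_usage.csv, run.log, config.json)
eegselect select --channels 8 --informative 1,4 --snr 3 --selector nsga2 \
    --generations 50 --out runs/nsga2 --seed 1

# NSGA vs backward elimination, aligned by channel count
eegselect compare --channels 6 --informative 2 --variant nsga3 --out runs/cmp

# pretty-print a result table
eegselect report runs/nsga2/pareto.csv
```

Real EDF input: replace the synthetic flags with
`--edf recording.edf --intervals seizures.csv`.

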