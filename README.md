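# mrcprel

Rater-reliability analysis of manual peak-negativity labelling in
movement-related cortical potentials (MRCPs).

## The problem

The MRCP is a slow (~0.5 Hz) negative EEG potential that builds up over the
1.5–2 s before a voluntary or imagined movement and peaks near movement
onset (amplitudes of roughly −5 to −30 µV). EEG-triggered interventions and
neurophysiological outcome measures both hinge on the *peak negativity*
(PN) — the most negative point of the averaged MRCP — which in practice is
found by a human expert who inspects 50 cue-locked epochs, rejects the ones
that do not look like MRCPs, averages the rest, and clicks on the PN. How
reliable is that manual process, and what drives disagreement?

`mrcprel` implements the full analysis pipeline for that question, for
researchers in EEG/ERP methodology and measurement reliability:

- **synthetic data** (`mrcprel.synthetic`) — condition-specific MRCP epochs
  (healthy voluntary, healthy imagined, stroke voluntary), continuous
  multi-channel recordings, and simulated raters with known ground truth,
  so the whole pipeline is testable without real EEG;
- **preprocessing** (`mrcprel.preprocessing`) — 0.05–5 Hz zero-phase
  second-order Butterworth band-pass, large Laplacian spatial filter
  centred on Cz (virtual channel = Cz − mean(Fz, Pz, C3, C4)), and
  extraction of 4.5 s cue-locked epochs (3 s pre, 1.5 s post at 500 Hz,
  cue at sample index 1500);
- **epoch metrics** (`mrcprel.epoch_metrics`) — the cosine similarity index
  cos(u, v) = u·v / (‖u‖‖v‖) of each epoch v against the average u of all
  50 epochs of its dataset; averaging of accepted epochs; automated PN
  labelling; matched-epoch tables (same rater accepting an epoch at two
  sessions, or all raters accepting it in one session);
- **reliability statistics** (`mrcprel.reliability`) — two-way ANOVA
  decomposition, the single-measures absolute-agreement two-way
  random-effects intraclass correlation

  ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

  its 95% F-based confidence interval, SEM = √MSE (ms), and the
  interpretation bands (>0.8 excellent, 0.6–0.8 good, 0.4–0.6 moderate,
  <0.4 poor);
- **association models** (`mrcprel.models`) — a random-intercept linear
  mixed model for cosine similarity across conditions with Tukey pairwise
  contrasts, and a random-intercept logistic mixed model (adaptive
  Gauss–Hermite quadrature) for the probability of a matched epoch as a
  function of cosine similarity, with likelihood-ratio interaction tests
  and probability curves;
- **pipeline + CLI** (`mrcprel.pipeline`, `mrcprel` command) — an
  end-to-end, seed-reproducible run writing diffable CSV/JSON artifacts.

## Worked example

```sh
python examples/01_simulate_and_similarity.py
```

```
healthy_voluntary   mean CS = 0.393 +- 0.176  (n = 500 epochs)
healthy_imagined    mean CS = 0.283 +- 0.146  (n = 500 epochs)
stroke_voluntary    mean CS = 0.424 +- 0.165  (n = 500 epochs)
```

Each line is one simulated study arm (10 datasets × 50 epochs): the mean
cosine similarity of single epochs to their dataset average. Voluntary
movement in healthy people and people with stroke produces consistent
epoch morphology (≈0.39–0.42); imagined movement is markedly less
consistent (≈0.27–0.28), which is what makes its epochs hard to select
reliably.

```sh
python examples/03_reliability_icc.py
```

```
intra-session (sessions 1 vs 2), one row per rater:
unit      icc   ci_low  ci_high       sem      band
  E1 0.986812 0.950158 0.996672 27.623460 excellent
  ...
inter-rater, one row per session:
    unit      icc   ci_low  ci_high       sem      band
session1 0.969458 0.927277 0.991148 38.976595 excellent
```

Each row is an ICC(A,1) with its 95% CI and the SEM in ms: with the default
(steady) simulated raters on voluntary-movement data, PN labelling is in
the excellent band with absolute errors of ~20–40 ms. The other examples
cover continuous-recording preprocessing (`02`) and the mixed-model trend
analysis with its similarity × condition interaction test (`04`).

The same analyses are available from a shell:

```sh
mrcprel report --seed 1 --out run1    # simulate → ... → report.json
mrcprel reliability --labels run1/labels.csv --design inter_rater \
    --condition healthy_voluntary --out icc.csv
```

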