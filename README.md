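# prpkit

Phoneme-level analysis of continuous-speech EEG, with synthetic ground
truth.

When listeners hear natural connected speech, each phoneme instance evokes
a weak, heavily overlapped cortical response.  Averaging the EEG time-locked
to every instance of one phoneme yields a **phoneme-related potential
(PRP)** — an `electrodes x time` summary of that phoneme's typical evoked
response — and the collection of a listener's PRPs carries a measurable
imprint of how *distinct* their cortical phoneme representations are.
Neuroscience of aging predicts that this distinctiveness declines
("neural dedifferentiation"): phonemes become harder to decode from the
PRPs, decoding grows more uncertain, the informative scalp topography
spreads out and slows down, and the representational geometry aligns less
with binary phonological features.

`prpkit` implements that entire analysis chain as a reusable, tested
Python package, and pairs it with a synthetic-EEG cohort generator whose
ground truth makes every stage falsifiable:

* **`prpkit.simulate`** — cohorts of continuous recordings with
  phoneme-locked templates organized by the manner features [syllabic],
  [sonorant], [continuant]; group-level manipulations of distinctiveness
  (α), spatial spread (σ), and latency (τ); envelope/onset-driven
  components with known convolution kernels; 1/f + white noise; covariates
  with controlled correlation to α.
* **`prpkit.prp`** — causal 1–15 Hz FIR filtering, mastoid re-referencing,
  frequency-balanced PRP extraction (instance cap with seeded re-draws).
* **`prpkit.decoder`** — an EEGNet-8,2-style compact CNN (pure NumPy,
  deterministic), stratified cross-validation with validation-loss
  checkpointing, Shannon-entropy uncertainty, group-balanced repetitions,
  confusion matrices.
* **`prpkit.relevance`** — reference-based attribution (rescale rule, exact
  completeness), relevance dispersion and peak latency.
* **`prpkit.rsa`** — feature/neural/confusion RDMs, Spearman alignment,
  relevance-ranked forward electrode selection, row-shuffle permutation
  tests, phoneme dendrograms (Newick).
* **`prpkit.tracking`** — 8-band envelope/onset predictors, sparse ℓ1
  boosting TRFs over −100..500 ms lags with segment-wise cross-validation,
  unique-variance Δr, data-defined ROI scores.
* **`prpkit.stats`** — PRP separability F-curves, cluster-mass permutation
  tests (electrodes or time), Welch / Mann-Whitney group tests,
  rationalized arcsine units, words-in-noise SNR loss, EHF log transform,
  backward stepwise AIC regression and residual group analysis.
* **`prpkit.pipeline` / `prpkit` CLI** — end-to-end orchestration with a
  machine-readable run report.

See `docs/methods.md` for the generative model, estimation details, and
numerical choices.

## Worked example

```python
import numpy as np
from scipy.stats import mannwhitneyu
from prpkit import desk_config, simulate_cohort, desk_spec, train_eval_cv
from prpkit.prp import preprocess_session, select_phonemes, extract_prps

cfg = desk_config(seed=1)          # 10+10 participants, alpha 1.2 vs 0.4
groups = {}
for s in simulate_cohort(cfg):
    clean, _ = preprocess_session(s)
    retained = select_phonemes(s.annotations)
    groups.setdefault(s.group, []).append(
        extract_prps(clean, s.fs, s.annotations, retained, seed=1,
                     participant_id=s.participant_id, group=s.group))

for g, prp_sets in groups.items():
    cv = train_eval_cv(prp_sets, desk_spec(), seed=1)
    pp = cv.per_participant()
    print(g, round(pp["accuracy"].mean(), 3), round(pp["entropy"].mean(), 3))

pa = mannwhitneyu(*[train_eval_cv(groups[g], desk_spec(), seed=1)
                    .per_participant()["accuracy"] for g in "AB"],
                  alternative="greater").pvalue
```

Output (about a minute on one CPU):

```
A 0.567 2.339
B 0.275 2.398
```

Group A (high distinctiveness) is decoded at 56.7% versus 27.5% for the
dedifferentiated group B — both far above the 8.3% chance level for 12
phonemes — and A's predictions carry lower Shannon entropy (2.34 vs 2.40
nats; the uniform bound is ln 12 ≈ 2.48).  The accuracy difference is
Mann-Whitney significant (p ≈ 1e-4).

The same cohort can be pushed through every downstream stage from the
shell:

```bash
prpkit run-all --preset desk --seed 1 --out runs/demo
```

which writes per-stage TSV/CSV/Newick outputs and `runs/demo/report.json`.

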