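# epinet

Low-dimensional EpiNet-saliency modelling for multichannel intracranial
EEG.

Localizing the epileptogenic network (EpiNet) — the patient-specific set
of brain regions generating epileptic dynamics — normally requires
recording seizures. Interictal biomarkers avoid that, but combining many
of them produces high-dimensional, hard-to-interpret feature spaces.
`epinet` implements a pipeline built on the hypothesis that the
epileptogenic signal in those features is intrinsically low-dimensional:

1. **Features.** From each channel, narrowband criticality features — the
   DFA exponent of long-range temporal correlations, a bistability index
   (BiS) of the amplitude distribution, and a functional
   excitation/inhibition index (fE/I) — over 20 Morlet bands (2–225 Hz),
   plus four phase-locking-value graph features — eigenvector centrality,
   effective weight, clustering coefficient, local efficiency — over 50
   bands (2–450 Hz): k = 260 features per channel.
2. **Eigenfeatures.** SVD of the pooled, within-subject-normalized
   feature matrix, X = U S V′; channel coefficients Φ = U′X are ranked by
   Cohen's *d* of the seizure-zone label contrast against label-shuffled
   surrogates, and the top r = 10 eigenfeatures are retained.
3. **Saliency model.** Consensus soft-clustering membership (Gaussian
   mixtures + Fuzzy C-means, averaged) is binned on the (Φ₁, Φ₂) plane
   (30 × 30) and fitted as a lookup surface: given a new channel's two
   leading coefficients it returns an EpiNet-saliency λ̂ ∈ [0, 1] — a
   > 99% reduction of the raw feature space with no retraining.
4. **Time-resolved application.** Sliding-window features of long sleep
   recordings are projected through the trained basis; λ̂(q, t), its
   channel mean Λ̂(t), and AUC(t) against labels track epileptogenic
   dynamics over hours.
5. **Validation.** Interictal-spike density (≥3 consecutive samples above
   7 SD in 0.5 s windows), spike-phase analyses, and canonical polyadic
   decomposition of the feature tensor (contact × feature × time)
   cross-validate the saliency estimates.

Clinical SEEG cannot be redistributed, so the package includes a
first-class synthetic-data generator (`epinet.synth`) that plants all of
the above structure — known Hurst exponents via exact fractional
Gaussian noise, telegraph bistability, gain-coupled E/I regimes, shared
phase drivers, Poisson spikes, ultradian sleep modulation — with full
ground truth. The test suite and the acceptance script run entirely on
it.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
import numpy as np
from epinet import CohortSpec, generate_cohort, PipelineConfig
from epinet.pipeline import fit_model, apply_model

config = PipelineConfig.reduced()   # desk-scale preset, same structure

# 1. simulate a small interictal training cohort with planted EpiNet channels
cohort = CohortSpec(n_subjects=4, channels_per_subject=20,
                    duration=600.0, sampling_rate=128.0, seed=7)
recordings, truth = generate_cohort(cohort)

# 2. train the saliency model (features -> SVD -> ranking -> membership -> surface)
model, info = fit_model(recordings, config, seed=0)
m, pos = model.membership, info["positive"]
print(f"coefficients above surrogate bounds: {model.latent.n_above_bounds()}")
print(f"rank-1 coefficient effect size d = "
      f"{abs(model.latent.effect_sizes[model.latent.ranking[0]]):.2f}")
print(f"consensus membership: EpiNet {m[pos].mean():.2f}, "
      f"background {m[~pos].mean():.2f}")

# 3. assess a held-out synthetic sleep recording time-resolved
sleep, sleep_truth = generate_cohort(
    CohortSpec(1, 20, 1800.0, 128.0, ultradian_period=10.0, seed=99),
    mode="sleep")
a = apply_model(model, sleep[0], config, window_s=120.0, step_s=60.0)
print(f"windows assessed: {a.lam.shape[1]}, peak AUC(t) = {np.nanmax(a.auc):.2f}")
```

Output:

```
coefficients above surrogate bounds: 1
rank-1 coefficient effect size d = 4.80
consensus membership: EpiNet 0.92, background 0.06
windows assessed: 29, peak AUC(t) = 1.00
```

One eigenfeature coefficient separates the planted pathological channels
far beyond the label-shuffle null (d = 4.8); the two-coefficient
saliency model assigns the planted EpiNet channels a consensus
membership near 1 and background channels near 0; and on an unseen
"sleep" recording the time-resolved saliency classifies channels
perfectly at the ultradian peaks.

The same workflow is available from the shell:

```bash
epinet simulate --mode interictal --subjects 4 --channels 20 \
       --duration 600 --fs 128 --seed 7 --out cohort/
epinet fit-model --recordings cohort/ --out model/
epinet simulate --mode sleep --subjects 1 --channels 20 \
       --duration 1800 --fs 128 --ultradian-period 10 --seed 99 --out sleep/
epinet apply --model model/model.epinet --recording sleep/sub-00.h5 \
       --window 120 --step 60 --out saliency/
epinet validate-tca --model model/model.epinet --recording sleep/sub-00.h5 \
       --out tca/
epinet report --apply-dir saliency/ --tca-dir tca/
```

See `docs/methods.md` for the model, estimator definitions, the
synthetic-data design, and numerical choices.

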