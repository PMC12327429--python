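"""Synthetic continuous-speech EEG cohorts with known ground truth.

The generator emulates the statistical structure that phoneme-level EEG
analyses assume, without modelling audio itself:

* every phoneme instance evokes a phoneme-specific template, built as
  ``common + alpha * (feature_part + beta * unique_part)`` where the feature
  part is a linear combination of three damped-oscillation time courses (one
  per binary manner feature, each with its own scalp map), the unique part is
  a smooth random pattern per phoneme, and ``common`` is a phoneme-independent
  auditory evoked response.  ``alpha`` is the distinctiveness parameter: at
  ``alpha = 0`` all phonemes evoke identical responses.
* spatial spread ``sigma``: only the ``ceil(sigma * E)`` electrodes with the
  largest aggregate template energy (one subset per participant) keep the
  phoneme-specific signal at full strength; the rest are attenuated by 90%.
  Each attenuated template is rescaled to its original Frobenius norm, so
  ``sigma`` moves signal *distribution* (localized vs. distributed), not
  signal energy.
* latency shift ``tau_ms`` delays the whole evoked template.
* band envelope / onset predictor series drive the recording through known
  convolution kernels (the acoustic-tracking ground truth).
* additive noise is a mixture of white and 1/f-shaped Gaussian noise.
* scalar covariates are coupled to each participant's realized ``alpha``
  through a Gaussian copula with exact Pearson control.

All randomness flows from one root seed split into per-participant streams,
so identical configurations reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .features import PhonemeFeatureTable, make_inventory

N_BANDS = 8


def disc_layout(n_electrodes: int) -> np.ndarray:
    """Deterministic sunflower layout of electrodes on the unit disc."""
    i = np.arange(n_electrodes)
    r = np.sqrt((i + 0.5) / n_electrodes)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@dataclass(frozen=True)
class GroupParams:
    """Generative manipulations applied to one participant group."""

    alpha: float          # template distinctiveness, >= 0
    sigma: float = 1.0    # fraction of electrodes carrying full signal, (0, 1]
    tau_ms: float = 0.0   # latency shift of the phoneme-specific part, ms >= 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.sigma <= 1:
            raise ValueError("sigma must lie in (0, 1]")
        if self.tau_ms < 0:
            raise ValueError("tau_ms must be >= 0")


@dataclass(frozen=True)
class CovariateSpec:
    """One scalar covariate with a target correlation to realized alpha."""

    name: str
    target_r: float = 0.0
    nuisance: bool = False
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if not -1.0 <= self.target_r <= 1.0:
            raise ValueError("target_r must lie in [-1, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a simulated cohort."""

    n_per_group: int
    group_params: dict                 # group label -> GroupParams
    n_electrodes: int = 16
    fs: float = 128.0
    n_segments: int = 8
    segment_s: float = 12.0
    inventory: PhonemeFeatureTable = None
    covariate_specs: tuple = ()
    noise_sd: float = 2.5              # µV
    pink_weight: float = 0.5           # 1/f share of noise variance, [0, 1]
    kernel_scale: float = 1.0          # scales the acoustic-tracking kernels
    alpha_rel_sd: float = 0.15         # participant-level variability of alpha
    unique_scale: float = 0.6          # beta: unique- vs feature-part amplitude
    common_scale: float = 0.25         # phoneme-independent evoked amplitude
    epoch_s: float = 0.5
    ioi_range: tuple = (0.05, 0.25)    # inter-onset interval bounds, s
    seed: int = 0

    def __post_init__(self):
        if self.n_electrodes < 4:
            raise ValueError("n_electrodes must be >= 4")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.inventory is None:
            object.__setattr__(self, "inventory", make_inventory(12, 0.7, seed=7))
        for gp in self.group_params.values():
            if not isinstance(gp, GroupParams):
                raise TypeError("group_params values must be GroupParams")
        if self.segment_s < self.epoch_s:
            raise ValueError(
                f"segment_s={self.segment_s} too short to hold one "
                f"{self.epoch_s}-s epoch")

    @property
    def layout(self) -> np.ndarray:
        return disc_layout(self.n_electrodes)

    @property
    def n_epoch_samples(self) -> int:
        return int(np.floor(self.epoch_s * self.fs))

    def alpha_population_moments(self) -> tuple:
        """Mean and SD of realized alpha over the whole cohort (mixture)."""
        alphas = np.array([gp.alpha for gp in self.group_params.values()])
        within_var = (alphas * self.alpha_rel_sd) ** 2
        mu = alphas.mean()
        var = within_var.mean() + np.var(alphas)
        return mu, np.sqrt(max(var, 1e-12))


@dataclass
class SimulatedSession:
    """One participant's continuous recording with annotations and truth."""

    participant_id: str
    group: str
    fs: float
    recording: np.ndarray              # (E + 2 mastoids) x N, µV
    ch_names: list
    annotations: pd.DataFrame          # onset_s, duration_s, phoneme
    predictors: np.ndarray             # 16 x N (8 band envelopes + 8 onsets)
    predictor_names: list
    segment_bounds: list               # [(start_sample, stop_sample), ...]
    covariates: dict
    truth: dict = field(repr=False)

    def validate(self):
        n = self.recording.shape[1]
        if not np.all(np.isfinite(self.recording)):
            raise ValueError("recording contains non-finite values")
        if np.any(self.predictors < -1e-12):
            raise ValueError("predictor series must be nonnegative")
        ons = self.annotations["onset_s"].to_numpy()
        if np.any(ons < 0) or np.any(ons >= n / self.fs):
            raise ValueError("annotation onsets outside the recording")
        labels = set(self.annotations["phoneme"])
        if not labels <= set(self.truth["inventory"]["labels"]):
            raise ValueError("annotation labels outside the inventory")
        return self


# --------------------------------------------------------------------------
# cohort-level generative structures (deterministic in config.seed)

def _gamma_pulse(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Smooth causal pulse peaking at t0 + width."""
    u = np.maximum(t - t0, 0.0) / width
    return u * np.exp(1.0 - u)

def _bump_map(layout: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    d2 = ((layout - center[None]) ** 2).sum(axis=1)
    return np.exp(-d2 / (2 * width ** 2))


def _cohort_structures(config: CohortConfig) -> dict:
    """Feature courses/maps, common response, unique parts, tracking kernels."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    E, fs, T = config.n_electrodes, config.fs, config.n_epoch_samples
    layout = config.layout
    t = np.arange(T) / fs

    # one damped oscillation per binary feature: heavy damping keeps the
    # first lobe dominant and the three latencies stay close together, so
    # the pooled phoneme-specific energy has a single well-defined peak
    # (a clean latency read-out for the relevance stage)
    freqs, lats = (4.0, 6.0, 8.0), (0.05, 0.08, 0.11)
    courses = []
    for fr, t0 in zip(freqs, lats):
        env = _gamma_pulse(t, t0, 0.06)
        courses.append(env * np.sin(2 * np.pi * fr * (t - t0)))
    courses = np.asarray(courses)                       # (3, T)
    courses *= 2.0 / np.linalg.norm(courses, axis=1, keepdims=True)
    # broad, mutually orthogonal scalp maps (monopolar bump plus two dipolar
    # gradients): the un-attenuated (sigma = 1) template is genuinely
    # distributed, and map orthogonality keeps template distances faithful
    # to the feature geometry even though the time courses overlap
    base = np.vstack([_bump_map(layout, np.zeros(2), 0.9),
                      layout[:, 0], layout[:, 1]])
    maps = np.linalg.qr(base.T)[0].T                    # (3, E) orthonormal
    maps = maps * np.sign(maps @ base.T).diagonal()[:, None]
    maps *= np.sqrt(E)                                  # O(1) per electrode

    # phoneme-independent auditory evoked response (N1-P2-like); kept small
    # relative to the phoneme-specific content so it does not dominate
    # attribution magnitudes
    common_course = config.common_scale * (
        -_gamma_pulse(t, 0.05, 0.05) + 0.7 * _gamma_pulse(t, 0.12, 0.09))
    common = _bump_map(layout, np.zeros(2), 0.9)[:, None] * common_course[None, :]

    feat = config.inventory.feature_matrix()            # (K, 3)
    feature_part = np.einsum("kf,fe,ft->ket", feat, maps, courses)

    # feature-part RMS sets the scale of the unique parts
    rms = np.sqrt(np.mean(feature_part ** 2))
    K = len(config.inventory.labels)
    unique = rng.normal(size=(K, E, T))
    unique = gaussian_filter1d(unique, sigma=max(1.0, 0.02 * fs), axis=-1)
    # temporal envelope keeps the phoneme-unique content in the same
    # 100-250 ms window as the feature courses, so the discriminative
    # signal (and hence attribution) has a well-defined peak latency
    unique *= _gamma_pulse(t, 0.05, 0.10)[None, None, :]
    unique *= rms / np.sqrt(np.mean(unique ** 2))

    # acoustic-tracking kernels: gamma-shaped courses on a central bump,
    # driving a subset of envelope and onset bands
    Lk = int(round(0.25 * fs))
    tk = np.arange(Lk) / fs
    kmap = _bump_map(layout, np.array([0.1, -0.2]), 0.5)
    kernels = np.zeros((2 * N_BANDS, E, Lk))
    for b in range(2, 6):
        kernels[b] = 0.4 * config.kernel_scale * kmap[:, None] \
            * _gamma_pulse(tk, 0.02, 0.06)[None, :]
        kernels[N_BANDS + b] = 0.6 * config.kernel_scale * kmap[:, None] \
            * _gamma_pulse(tk, 0.01, 0.035)[None, :]

    return {"courses": courses, "maps": maps, "common": common,
            "feature_part": feature_part, "unique": unique,
            "kernels": kernels, "layout": layout}


def participant_templates(config: CohortConfig, group: str,
                          alpha_i: float, structures: dict | None = None) -> dict:
    """Per-phoneme E x T truth templates for one participant."""
    s = structures or _cohort_structures(config)
    gp = config.group_params[group]
    E, T = config.n_electrodes, config.n_epoch_samples
    shift = int(round(gp.tau_ms / 1000.0 * config.fs))
    keep = int(np.ceil(gp.sigma * E))
    specs = {}
    for k, label in enumerate(config.inventory.labels):
        specs[label] = alpha_i * (s["feature_part"][k]
                                  + config.unique_scale * s["unique"][k])
    if keep < E:
        # one electrode subset per participant (aggregate template energy),
        # so localization is consistent across phonemes; rescaling preserves
        # each phoneme's template energy
        energy = np.sum([(m ** 2).sum(axis=1) for m in specs.values()], axis=0)
        top = np.argsort(energy)[::-1][:keep]
        att = np.full(E, 0.1)
        att[top] = 1.0
        for label, spec in specs.items():
            norm0 = np.linalg.norm(spec)
            spec = spec * att[:, None]
            nrm = np.linalg.norm(spec)
            specs[label] = spec * (norm0 / nrm if nrm > 0 else 1.0)
    out = {}
    for label, spec in specs.items():
        full = s["common"] + spec
        if shift > 0:       # the whole evoked template is delayed by tau
            full = np.pad(full, [(0, 0), (shift, 0)])[:, :T]
        out[label] = full
    return out


# --------------------------------------------------------------------------
# per-participant draws

def draw_participant(config: CohortConfig, group: str, participant_seed: int):
    """Realized alpha and covariates for one participant.

    Covariates couple to the pooled-standardized alpha through a Gaussian
    copula, so each non-nuisance covariate attains its target Pearson
    correlation with alpha in expectation; nuisance covariates are
    independent of alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence([participant_seed, 0xA1FA]))
    gp = config.group_params[group]
    z = rng.normal()
    alpha_i = max(gp.alpha * (1.0 + config.alpha_rel_sd * z), 0.0)
    mu, sd = config.alpha_population_moments()
    z_pool = (alpha_i - mu) / sd
    cov = {}
    for spec in config.covariate_specs:
        eps = rng.normal()
        if spec.nuisance or spec.target_r == 0.0:
            val = eps
        else:
            val = spec.target_r * z_pool + np.sqrt(1 - spec.target_r ** 2) * eps
        cov[spec.name] = spec.mean + spec.sd * val
    return alpha_i, cov


def _pink_noise(rng, shape, n):
    """Unit-variance 1/f-shaped Gaussian noise along the last axis."""
    white = rng.normal(size=shape + (n,))
    f = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        scale = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, 1e-12)), 0.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n, axis=-1)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _band_predictors(rng, n, fs):
    """8 nonnegative band envelopes with speech-like co-modulation + onsets."""
    smooth = max(1.0, 0.03 * fs)
    glob = gaussian_filter1d(np.abs(rng.normal(size=n)), smooth)
    env = np.empty((N_BANDS, n))
    for b in range(N_BANDS):
        own = gaussian_filter1d(np.abs(rng.normal(size=n)), smooth)
        env[b] = 0.5 * glob + 0.5 * own
    env /= env.mean()
    onset = np.maximum(np.diff(env, axis=1, prepend=env[:, :1]), 0.0)
    return np.vstack([env, onset])


def simulate_session(config: CohortConfig, group: str,
                     participant_seed: int,
                     participant_id: str | None = None) -> SimulatedSession:
    """Generate one participant's continuous recording.

    The recording is the superposition of (i) the phoneme template stream,
    (ii) the kernel-convolved predictor stream, and (iii) white + 1/f noise;
    the truth block stores every generative quantity needed to reconstruct
    the noise-free signal.
    """
    if group not in config.group_params:
        raise KeyError(f"unknown group {group!r}")
    structures = _cohort_structures(config)
    rng = np.random.default_rng(np.random.SeedSequence([participant_seed, 0x5E55]))
    fs, E = config.fs, config.n_electrodes
    seg_n = int(round(config.segment_s * fs))
    n = seg_n * config.n_segments
    T = config.n_epoch_samples

    alpha_i, covariates = draw_participant(config, group, participant_seed)
    templates = participant_templates(config, group, alpha_i, structures)

    # annotations: instances tile each segment with uniform IOIs
    lo, hi = config.ioi_range
    labels_arr = list(config.inventory.labels)
    rows = []
    for seg in range(config.n_segments):
        t_cur = float(rng.uniform(lo, hi))
        while t_cur + config.epoch_s < config.segment_s:
            ioi = float(rng.uniform(lo, hi))
            lab = labels_arr[rng.choice(len(labels_arr), p=config.inventory.weights)]
            rows.append((seg * config.segment_s + t_cur, ioi, lab))
            t_cur += ioi
    annotations = pd.DataFrame(rows, columns=["onset_s", "duration_s", "phoneme"])

    template_stream = np.zeros((E, n))
    for onset, _, lab in annotations.itertuples(index=False):
        s0 = int(round(onset * fs))
        w = min(T, n - s0)
        if w > 0:
            template_stream[:, s0:s0 + w] += templates[lab][:, :w]

    predictors = _band_predictors(rng, n, fs)
    kernels = structures["kernels"]
    kernel_stream = np.zeros((E, n))
    Lk = kernels.shape[-1]
    for q in range(predictors.shape[0]):
        if np.any(kernels[q]):
            conv = np.apply_along_axis(
                lambda k: np.convolve(predictors[q], k)[:n], 1, kernels[q])
            kernel_stream += conv

    noise = np.zeros((E + 2, n))
    if config.noise_sd > 0:
        w = config.pink_weight
        white = rng.normal(size=(E + 2, n))
        pink = _pink_noise(rng, (E + 2,), n)
        noise = config.noise_sd * (np.sqrt(1 - w) * white + np.sqrt(w) * pink)

    recording = noise
    recording[:E] += template_stream + kernel_stream

    gp = config.group_params[group]
    truth = {
        "alpha": alpha_i,
        "group_params": {"alpha": gp.alpha, "sigma": gp.sigma, "tau_ms": gp.tau_ms},
        "templates": templates,
        "kernels": kernels,
        "layout": structures["layout"],
        "inventory": config.inventory.to_dict(),
        "participant_seed": participant_seed,
    }
    ch_names = [f"E{i:02d}" for i in range(E)] + ["M1", "M2"]
    pred_names = [f"env{b}" for b in range(N_BANDS)] + \
                 [f"onset{b}" for b in range(N_BANDS)]
    session = SimulatedSession(
        participant_id=participant_id or f"{group}-{participant_seed}",
        group=group, fs=fs, recording=recording, ch_names=ch_names,
        annotations=annotations, predictors=predictors,
        predictor_names=pred_names,
        segment_bounds=[(s * seg_n, (s + 1) * seg_n) for s in range(config.n_segments)],
        covariates=covariates, truth=truth)
    return session.validate()


def simulate_cohort(config: CohortConfig) -> list:
    """Generate ``n_per_group`` sessions per group from the root seed."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_per_group * len(config.group_params))
    sessions = []
    i = 0
    for group in config.group_params:
        for j in range(config.n_per_group):
            sessions.append(simulate_session(
                config, group, int(seeds[i] % (2 ** 31)),
                participant_id=f"{group}{j:02d}"))
            i += 1
    return sessions


# --------------------------------------------------------------------------
# reference study conditions

def default_covariates() -> tuple:
    """Covariate battery mirroring an auditory aging study.

    ``abr_wave_i`` is the driver coupled to distinctiveness (its empirical
    analogue predicts phoneme decoding accuracy); the rest are nuisance
    stand-ins (no coupling).
    """
    return (
        CovariateSpec("abr_wave_i", target_r=0.7, mean=0.33, sd=0.17),
        CovariateSpec("abr_wave_v", nuisance=True, mean=0.28, sd=0.15),
        CovariateSpec("pta", nuisance=True, mean=8.0, sd=4.0),
        CovariateSpec("ehf_threshold", nuisance=True, mean=6.0, sd=9.0),
        CovariateSpec("moca", nuisance=True, mean=27.5, sd=1.8),
        CovariateSpec("ospan", nuisance=True, mean=46.0, sd=15.0),
    )


def desk_config(seed: int = 0, **overrides) -> CohortConfig:
    """Desk-scale study conditions (two groups, strong dedifferentiation).

    Group A emulates younger listeners (distinct, localized, early);
    group B emulates middle-aged listeners (less distinct, spatially
    distributed, delayed by 80 ms).
    """
    base = dict(
        n_per_group=10,
        group_params={
            "A": GroupParams(alpha=1.2, sigma=0.25, tau_ms=0.0),
            "B": GroupParams(alpha=0.4, sigma=1.0, tau_ms=80.0),
        },
        n_electrodes=16, fs=64.0, n_segments=8, segment_s=12.0,
        inventory=make_inventory(12, 0.7, seed=7),
        covariate_specs=default_covariates(),
        noise_sd=2.5, pink_weight=0.5, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)


def paper_scale_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-scale preset (61 electrodes, 31 phonemes, 128 Hz)."""
    base = dict(
        n_per_group=20,
        group_params={
            "A": GroupParams(alpha=1.2, sigma=0.25, tau_ms=0.0),
            "B": GroupParams(alpha=0.4, sigma=1.0, tau_ms=80.0),
        },
        n_electrodes=61, fs=128.0, n_segments=15, segment_s=60.0,
        inventory=make_inventory(31, 1.0, seed=7),
        covariate_specs=default_covariates(),
        noise_sd=2.5, pink_weight=0.5, seed=seed)
    base.update(overrides)
    return CohortConfig(**base)
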