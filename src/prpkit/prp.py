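"""Preprocessing and phoneme-related potential (PRP) derivation.

A PRP is the average of EEG epochs time-locked to all instances of one
phoneme in continuous speech: a compact ``electrodes x time`` summary of the
typical evoked response to that phoneme.  Preprocessing is deliberately
minimal — a causal (minimum-phase) FIR band-pass of 1–15 Hz and mastoid
re-referencing — matching what continuous-speech decoding pipelines apply
before epoching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import firwin, minimum_phase, lfilter

logger = logging.getLogger(__name__)


def bandpass_taps(fs: float, lo: float = 1.0, hi: float = 15.0) -> np.ndarray:
    """Minimum-phase causal FIR band-pass (windowed-sinc design)."""
    if fs < 64:
        raise ValueError(f"fs must be >= 64 Hz (got {fs})")
    # linear-phase prototype; length scaled to the low transition band
    n_taps = int(round(3.3 * fs / lo)) | 1
    lin = firwin(n_taps, [lo, min(hi, 0.45 * fs)], pass_zero=False, fs=fs)
    return minimum_phase(lin, method="hilbert")


def preprocess(recording: np.ndarray, fs: float, ch_names: list,
               mastoids: tuple = ("M1", "M2"),
               band: tuple = (1.0, 15.0)):
    """Filter and re-reference a continuous recording.

    Applies the causal band-pass to every channel, subtracts the average of
    the two mastoid channels from all channels, and drops the mastoids from
    the output.

    Returns ``(clean, kept_names)`` where ``clean`` is (E, N).
    """
    recording = np.asarray(recording, dtype=float)
    missing = [m for m in mastoids if m not in ch_names]
    if missing:
        raise ValueError(f"mastoid channels not found: {missing}; "
                         "designate two reference channels")
    taps = bandpass_taps(fs, *band)
    filtered = lfilter(taps, 1.0, recording, axis=-1)
    m_idx = [ch_names.index(m) for m in mastoids]
    ref = filtered[m_idx].mean(axis=0)
    rereferenced = filtered - ref[None, :]
    keep = [i for i, name in enumerate(ch_names) if name not in mastoids]
    return rereferenced[keep], [ch_names[i] for i in keep]


def preprocess_session(session, band: tuple = (1.0, 15.0)):
    """Convenience wrapper for :class:`~prpkit.simulate.SimulatedSession`."""
    return preprocess(session.recording, session.fs, session.ch_names, band=band)


def select_phonemes(annotations: pd.DataFrame, min_fraction: float = 0.01,
                    exclude: set = frozenset()) -> list:
    """Labels whose instance count strictly exceeds ``min_fraction`` of all.

    Mirrors the retention rule of frequency-balanced PRP analyses: drop
    rare phonemes (unreliable averages) and any explicitly excluded,
    over-frequent label.  Returns the retained labels alphabetically.
    """
    if len(annotations) == 0:
        raise ValueError("annotations are empty")
    counts = annotations["phoneme"].value_counts()
    total = int(counts.sum())
    kept = sorted(lab for lab, c in counts.items()
                  if c > min_fraction * total and lab not in exclude)
    if not kept:
        raise ValueError(
            f"no phoneme exceeds min_fraction={min_fraction} of {total} "
            f"instances (exclude={sorted(exclude)})")
    return kept


@dataclass
class PRPSet:
    """Per-participant mapping phoneme -> averaged E x T response."""

    participant_id: str
    group: str
    fs: float
    window: tuple                      # (start_s, end_s) relative to onset
    prps: dict = field(repr=False)     # label -> (E, T) µV
    counts: dict = field(default_factory=dict)

    @property
    def labels(self) -> list:
        return sorted(self.prps)

    @property
    def n_times(self) -> int:
        return next(iter(self.prps.values())).shape[1]

    def stack(self, labels=None) -> np.ndarray:
        """(K, E, T) array in the given (default: sorted) label order."""
        labels = labels or self.labels
        return np.stack([self.prps[lab] for lab in labels])


def extract_prps(recording: np.ndarray, fs: float, annotations: pd.DataFrame,
                 retained: list, cap: int = 319,
                 window: tuple = (0.0, 0.5), seed: int = 0,
                 participant_id: str = "", group: str = "") -> PRPSet:
    """Average epochs per phoneme with a random instance cap.

    Epochs span the half-open window ``[onset + start, onset + end)`` so the
    sample count is exactly ``floor((end - start) * fs)``.  Phonemes with more
    than ``cap`` complete epochs contribute a seeded uniform random subset of
    size ``cap`` (sampling without replacement); epochs running past the end
    of the recording are dropped (count logged).
    """
    rng = np.random.default_rng(seed)
    start, end = window
    T = int(np.floor((end - start) * fs))
    n = recording.shape[1]
    prps, counts = {}, {}
    n_dropped = 0
    by_label = annotations.groupby("phoneme")["onset_s"]
    for lab in retained:
        if lab not in by_label.groups:
            raise ValueError(f"retained label {lab!r} absent from annotations")
        onsets = by_label.get_group(lab).to_numpy()
        s0 = np.round((onsets + start) * fs).astype(int)
        complete = s0[(s0 >= 0) & (s0 + T <= n)]
        n_dropped += len(s0) - len(complete)
        if len(complete) == 0:
            raise ValueError(f"label {lab!r} has no complete epochs")
        if len(complete) > cap:
            complete = complete[rng.choice(len(complete), size=cap, replace=False)]
        acc = np.zeros((recording.shape[0], T))
        for s in complete:
            acc += recording[:, s:s + T]
        prps[lab] = acc / len(complete)
        counts[lab] = int(len(complete))
    if n_dropped:
        logger.info("extract_prps: dropped %d incomplete edge epochs", n_dropped)
    return PRPSet(participant_id=participant_id, group=group, fs=fs,
                  window=window, prps=prps, counts=counts)
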