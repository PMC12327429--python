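"""Phoneme inventories with binary manner features and Zipf-like frequencies.

Phonemes are characterized by three binary distinctive features that capture
the major manner-of-articulation classes:

* ``syllabic``   — vowels (1) vs. consonants (0)
* ``sonorant``   — approximants/nasals (1) vs. obstruents (0), among consonants
* ``continuant`` — open oral tract (1): vowels, approximants, fricatives, vs.
  closed (0): nasals, stops

The presence/absence of a feature is coded 1/0, so every phoneme maps to a
0/1 triple and phonemes sharing a manner class share (most of) the triple.
Relative frequencies follow a Zipf law, mirroring the strongly skewed phoneme
frequency distribution of natural speech.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURE_NAMES = ("syllabic", "sonorant", "continuant")

#: feature triple per manner class
MANNER_FEATURES = {
    "vowel": (1, 1, 1),
    "approximant": (0, 1, 1),
    "nasal": (0, 1, 0),
    "fricative": (0, 0, 1),
    "stop": (0, 0, 0),
}

# ARPABET-style label pools per manner class, used to draw inventories.
_POOLS = {
    "vowel": ["AA", "AE", "AO", "EH", "ER", "IH", "IY", "OW", "UH", "UW", "AY", "EY"],
    "approximant": ["L", "R", "W", "Y"],
    "nasal": ["M", "N", "NG"],
    "fricative": ["S", "Z", "F", "V", "SH", "TH", "DH", "ZH", "HH"],
    "stop": ["P", "B", "T", "D", "K", "G", "CH", "JH"],
}

# cycle order guaranteeing that all four major manner classes appear
# as soon as n_phonemes >= 4 (approximants and nasals share a class)
_CLASS_CYCLE = ("vowel", "approximant", "fricative", "stop", "nasal")


@dataclass(frozen=True)
class PhonemeFeatureTable:
    """Inventory of phonemes with binary features and relative frequencies.

    Attributes
    ----------
    labels : tuple of str
        Unique phoneme identifiers, ordered from most to least frequent.
    features : dict
        ``label -> (syllabic, sonorant, continuant)`` with values in {0, 1}.
    weights : numpy.ndarray
        Relative frequency per label (same order as ``labels``); strictly
        positive, summing to 1.
    """

    labels: tuple
    features: dict
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("phoneme labels must be unique")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels),):
            raise ValueError("weights must align with labels")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be strictly positive and sum to 1")
        for lab in self.labels:
            trip = self.features[lab]
            if len(trip) != 3 or any(v not in (0, 1) for v in trip):
                raise ValueError(f"feature triple of {lab!r} must be three 0/1 values")
        object.__setattr__(self, "weights", w)

    def feature_matrix(self, subset=None) -> np.ndarray:
        """Return a K x F 0/1 matrix, columns restricted to ``subset`` names."""
        names = FEATURE_NAMES if subset is None else tuple(subset)
        for name in names:
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {name!r}; valid: {FEATURE_NAMES}")
        idx = [FEATURE_NAMES.index(n) for n in names]
        return np.array([[self.features[lab][i] for i in idx] for lab in self.labels],
                        dtype=float)

    def manner_class(self, label: str) -> str:
        trip = tuple(self.features[label])
        for cls, feats in MANNER_FEATURES.items():
            if feats == trip:
                return cls
        return "other"

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "features": {lab: list(self.features[lab]) for lab in self.labels},
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhonemeFeatureTable":
        return cls(labels=tuple(d["labels"]),
                   features={k: tuple(v) for k, v in d["features"].items()},
                   weights=np.asarray(d["weights"], dtype=float))


def make_inventory(n_phonemes: int, zipf_exponent: float = 1.0,
                   seed: int = 0) -> PhonemeFeatureTable:
    """Draw a phoneme inventory whose frequencies follow a Zipf law.

    Labels are taken from ARPABET-style pools cycling through the manner
    classes so that the four major classes (vowels, approximants/nasals,
    fricatives, stops) are all represented whenever ``n_phonemes >= 4``.
    The rank-r weight is proportional to ``r ** -zipf_exponent``.

    Parameters
    ----------
    n_phonemes : int
        Inventory size; must be at least 4.
    zipf_exponent : float
        Skew of the frequency distribution (0 = flat).
    seed : int
        Controls which label receives which frequency rank.
    """
    if n_phonemes < 4:
        raise ValueError(f"n_phonemes must be >= 4 (got {n_phonemes})")
    rng = np.random.default_rng(seed)
    pools = {cls: list(rng.permutation(p)) for cls, p in _POOLS.items()}
    chosen, classes = [], []
    i = 0
    while len(chosen) < n_phonemes:
        cls = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        i += 1
        if pools[cls]:
            chosen.append(pools[cls].pop())
            classes.append(cls)
        elif all(not p for p in pools.values()):
            # pools exhausted: synthesize extra labels, keep cycling classes
            chosen.append(f"{cls[:2].upper()}{len(chosen)}")
            classes.append(cls)
    order = rng.permutation(n_phonemes)  # which label gets which rank
    labels = tuple(chosen[j] for j in order)
    feats = {chosen[j]: MANNER_FEATURES[classes[j]] for j in order}
    ranks = np.arange(1, n_phonemes + 1, dtype=float)
    w = ranks ** (-float(zipf_exponent))
    w /= w.sum()
    return PhonemeFeatureTable(labels=labels, features=feats, weights=w)
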