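"""Attribution of classifier decisions back to electrodes x time.

Contribution scores are obtained by backpropagating reference-based
multipliers (rescale rule) from the target phoneme's pre-soft-max output to
the PRP input, against an all-zero reference — the natural rest point of a
band-passed, baseline-free signal.  The scores satisfy the completeness
axiom: they sum to the difference between the target logit at the input and
at the reference.  Positive and negative values denote evidence for and
against the target phoneme.

Relevance summaries ignore the sign of evidence: absolute scores are
z-transformed within each matrix, averaged across phonemes (and, when
available, repetitions) into one E x T map per participant, from which two
statistics are derived: *dispersion* (variance of time-averaged relevance
between electrodes; smaller = more spatially distributed processing) and
*peak latency* (time at which electrode-averaged relevance is maximal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decoder import CVResult
from .prp import PRPSet


def attribute(model, prp: np.ndarray, target: int,
              rule: str = "rescale",
              completeness_tol: float = 1e-3) -> np.ndarray:
    """E x T contribution scores of one PRP toward the target phoneme.

    Raises if the completeness identity (sum of contributions equals the
    target-logit difference between input and reference) is violated beyond
    ``completeness_tol`` relative tolerance — that signals an implementation
    bug, not a data problem.
    """
    prp = np.asarray(prp, dtype=float)
    contrib = model.attribute(prp, target, rule=rule)
    if rule == "rescale":
        delta = (model.logits(prp[None])[0, target]
                 - model.logits(np.zeros_like(prp)[None])[0, target])
        err = abs(contrib.sum() - delta)
        if err > completeness_tol * max(abs(delta), 1e-6):
            raise AssertionError(
                f"completeness violated: sum={contrib.sum():.6g} vs "
                f"delta={delta:.6g} (err {err:.3g})")
    return contrib


@dataclass
class RelevanceMap:
    """Per-participant relevance of each electrode over time."""

    participant_id: str
    group: str
    fs: float
    scores: np.ndarray = field(repr=False)    # (E, T), z-scored |contributions|
    n_matrices: int = 0

    @property
    def dispersion(self) -> float:
        return dispersion(self)

    @property
    def peak_latency_ms(self) -> float:
        return peak_latency(self)[0]


def _z_abs(mat: np.ndarray) -> np.ndarray | None:
    """Absolute values, then z-transform over all entries; None if degenerate."""
    a = np.abs(mat)
    sd = a.std()
    if sd == 0:
        return None
    return (a - a.mean()) / sd


def relevance_map(cv: CVResult, prp_sets: list, participant_id: str,
                  rule: str = "rescale") -> RelevanceMap | None:
    """Average z-scored absolute attributions for one participant.

    Each of the participant's (phoneme, repetition) PRPs is attributed with
    the model of the test fold it belonged to (no train/test leakage), the
    absolute scores are z-transformed within each matrix, and the matrices
    are averaged.  Returns None (with a warning) if every matrix is
    degenerate (zero variance).
    """
    if cv.models is None:
        raise ValueError("train_eval_cv must be called with return_models=True")
    from .decoder import _standardize
    lab_idx = {lab: k for k, lab in enumerate(cv.labels)}
    prp_set = next(s for s in prp_sets if s.participant_id == participant_id)
    rec = cv.records
    mats = []
    mask = rec["participant"] == participant_id
    for row_pos, row in zip(np.flatnonzero(mask.to_numpy()), rec[mask].itertuples()):
        model = cv.models[int(row.fold)]
        x = _standardize(prp_set.prps[row.true])
        contrib = attribute(model, x, lab_idx[row.true], rule=rule)
        z = _z_abs(contrib)
        if z is not None:
            mats.append(z)
    if not mats:
        warnings.warn(f"all attribution matrices degenerate for "
                      f"{participant_id}; map excluded")
        return None
    return RelevanceMap(participant_id=participant_id, group=prp_set.group,
                        fs=prp_set.fs, scores=np.mean(mats, axis=0),
                        n_matrices=len(mats))


def average_maps(maps: list) -> RelevanceMap:
    """Average several maps of one participant (e.g., across repetitions)."""
    maps = [m for m in maps if m is not None]
    if not maps:
        raise ValueError("no valid maps to average")
    first = maps[0]
    return RelevanceMap(participant_id=first.participant_id, group=first.group,
                        fs=first.fs,
                        scores=np.mean([m.scores for m in maps], axis=0),
                        n_matrices=sum(m.n_matrices for m in maps))


def dispersion(rmap: RelevanceMap) -> float:
    """Variance (ddof=1) between electrodes of time-averaged relevance."""
    per_electrode = rmap.scores.mean(axis=1)
    if per_electrode.size < 2:
        raise ValueError("dispersion needs at least 2 electrodes")
    return float(np.var(per_electrode, ddof=1))


def peak_latency(rmap: RelevanceMap) -> tuple:
    """Latency (ms after PRP onset) of the electrode-averaged relevance peak.

    Ties resolve to the earliest index; returns ``(latency_ms, tied)``.
    """
    course = rmap.scores.mean(axis=0)
    idx = int(np.argmax(course))
    tied = bool(np.sum(course == course[idx]) > 1)
    return 1000.0 * idx / rmap.fs, tied


def electrode_ranking(maps: list) -> np.ndarray:
    """Electrode indices ranked by group-mean time-averaged relevance."""
    mean_scores = np.mean([m.scores.mean(axis=1) for m in maps], axis=0)
    return np.argsort(mean_scores)[::-1]
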