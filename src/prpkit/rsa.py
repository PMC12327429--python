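"""Representational similarity analysis of phoneme responses.

Dissimilarity matrices (RDMs) are built from three sources: binary
phonological feature vectors (Euclidean distance), PRP electrode patterns at
each time step (Euclidean distance), and classifier confusion matrices
(symmetrized confusion probability, complemented).  Alignment between a
neural RDM series and a feature RDM is the Spearman rank correlation of
their strict upper triangles per time step; a forward electrode-selection
procedure grows the electrode set by relevance rank while the overall
(time- and participant-averaged) alignment keeps improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .features import PhonemeFeatureTable
from .prp import PRPSet


@dataclass
class RDM:
    """Symmetric condition-by-condition dissimilarities, zero diagonal."""

    labels: list
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("RDM must be symmetric")
        if np.abs(np.diag(m)).max() != 0:
            raise ValueError("RDM diagonal must be exactly 0")
        if np.any(m < 0):
            raise ValueError("dissimilarities must be nonnegative")
        self.matrix = m

    def upper(self) -> np.ndarray:
        """Vectorized strict upper triangle."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]

    def reorder(self, labels) -> "RDM":
        """The same RDM with rows/columns in the given label order."""
        if list(labels) == list(self.labels):
            return self
        idx = [self.labels.index(lab) for lab in labels]
        return RDM(labels=list(labels), matrix=self.matrix[np.ix_(idx, idx)])


def feature_rdm(table: PhonemeFeatureTable, feature_subset=None) -> RDM:
    """Pairwise Euclidean distances between 0/1 feature vectors."""
    vecs = table.feature_matrix(feature_subset)
    return RDM(labels=list(table.labels), matrix=squareform(pdist(vecs)))


def neural_rdm_series(prp_set: PRPSet, electrodes=None) -> list:
    """One RDM per time step from electrode-pattern distances of the PRPs."""
    labels = prp_set.labels
    if len(labels) < 3:
        raise ValueError("need at least 3 phonemes")
    stack = prp_set.stack(labels)                       # (K, E, T)
    if electrodes is not None:
        electrodes = np.asarray(electrodes, dtype=int)
        if electrodes.size == 0:
            raise ValueError("electrode subset is empty")
        stack = stack[:, electrodes, :]
    if stack.shape[1] < 1:
        raise ValueError("need at least 1 electrode")
    out = []
    for t in range(stack.shape[2]):
        out.append(RDM(labels=labels, matrix=squareform(pdist(stack[:, :, t]))))
    return out


@dataclass
class AlignmentCurve:
    """Spearman alignment of neural RDMs to a feature RDM over time."""

    participant_id: str
    time_s: np.ndarray
    rho: np.ndarray
    degenerate: np.ndarray = field(default=None)
    electrodes: np.ndarray = field(default=None)


def _spearman_triu(a: np.ndarray, b: np.ndarray) -> tuple:
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return 0.0, True
    rho = stats.spearmanr(a, b).statistic
    return float(rho), False


def alignment(neural: list, feature: RDM, fs: float = None,
              participant_id: str = "") -> AlignmentCurve:
    """Spearman rho per time step between neural and feature RDMs.

    Computed on the strict upper triangles (the diagonal and duplicate
    entries carry no information).  A constant RDM at some time step yields
    rho = 0 with its degeneracy flagged.
    """
    if neural and set(neural[0].labels) != set(feature.labels):
        raise ValueError("neural and feature RDM labels differ")
    fu = feature.reorder(neural[0].labels).upper() if neural else None
    rhos, degen = [], []
    for r in neural:
        rho, d = _spearman_triu(r.upper(), fu)
        rhos.append(rho)
        degen.append(d)
    n = len(rhos)
    time_s = np.arange(n) / fs if fs else np.arange(n, dtype=float)
    return AlignmentCurve(participant_id=participant_id, time_s=time_s,
                          rho=np.asarray(rhos), degenerate=np.asarray(degen))


def overall_rho(prp_sets: list, electrodes, feature: RDM) -> float:
    """Alignment averaged over time and participants for one electrode set."""
    vals = []
    for s in prp_sets:
        curve = alignment(neural_rdm_series(s, electrodes), feature, fs=s.fs)
        vals.append(curve.rho.mean())
    return float(np.mean(vals))


def forward_select(prp_sets: list, ranked_electrodes, feature: RDM) -> tuple:
    """Grow the electrode set by relevance rank while alignment improves.

    Starts from the two most relevant electrodes, then repeatedly adds the
    next-ranked electrode; stops the first time the overall rho fails to
    strictly increase.  Returns ``(electrode_set, best_rho, trace)``.
    """
    ranked = list(ranked_electrodes)
    if len(ranked) < 2:
        raise ValueError("need at least 2 ranked electrodes")
    current = ranked[:2]
    best = overall_rho(prp_sets, current, feature)
    trace = [(tuple(current), best)]
    for e in ranked[2:]:
        cand = current + [e]
        rho = overall_rho(prp_sets, cand, feature)
        trace.append((tuple(cand), rho))
        if rho > best:
            current, best = cand, rho
        else:
            break
    return np.asarray(current, dtype=int), best, trace


def confusion_rdm(confusion: np.ndarray, labels: list) -> RDM:
    """RDM from a confusion-count matrix.

    Rows are normalized to conditional confusion probabilities, symmetrized
    as (P + P')/2, and complemented (1 - similarity) with the diagonal
    forced to zero.
    """
    c = np.asarray(confusion, dtype=float)
    sums = c.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"zero confusion row(s) for: "
                         f"{[labels[i] for i in zero]}")
    p = c / sums[:, None]
    sim = 0.5 * (p + p.T)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)   # exact symmetry against float noise
    return RDM(labels=list(labels), matrix=d)


def rho_of_confusion(confusion: np.ndarray, feature: RDM) -> float:
    rdm = confusion_rdm(confusion, feature.labels)
    rho, _ = _spearman_triu(rdm.upper(), feature.upper())
    return rho


def permutation_rho_difference(conf_a: np.ndarray, conf_b: np.ndarray,
                               feature: RDM, n_perm: int = 5000,
                               seed: int = 0) -> dict:
    """Row-shuffle permutation test of the confusion-RDM alignment difference.

    The observed statistic is rho(A) - rho(B).  Each permutation shuffles the
    rows of both confusion matrices independently and recomputes the
    difference; p is the proportion of null differences smaller than the
    observed one (one-sided, as printed).
    """
    import warnings
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for a permutation test")
    observed = rho_of_confusion(conf_a, feature) - rho_of_confusion(conf_b, feature)
    rng = np.random.default_rng(seed)
    K = conf_a.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = rng.permutation(K)
        pb = rng.permutation(K)
        null[i] = (rho_of_confusion(conf_a[pa], feature)
                   - rho_of_confusion(conf_b[pb], feature))
    p = float(np.mean(null < observed))
    return {"observed": observed, "p": p, "null": null}


def phoneme_dendrogram(prp_set: PRPSet, electrodes=None,
                       window: tuple = (0.0, 0.35)) -> dict:
    """Average-linkage clustering of phonemes from windowed PRP patterns.

    PRPs are flattened over (electrodes x window samples) and clustered on
    pairwise Euclidean distances.  Returns the labels, the SciPy linkage
    matrix, and a Newick string of the merge tree.
    """
    labels = prp_set.labels
    if len(labels) < 3:
        raise ValueError("need at least 3 phonemes to cluster")
    t0 = int(np.floor((window[0] - prp_set.window[0]) * prp_set.fs))
    t1 = int(np.floor((window[1] - prp_set.window[0]) * prp_set.fs))
    if t0 < 0 or t1 > prp_set.n_times or t0 >= t1:
        raise ValueError(f"window {window} outside the PRP range "
                         f"{prp_set.window}")
    stack = prp_set.stack(labels)[:, :, t0:t1]
    if electrodes is not None:
        stack = stack[:, np.asarray(electrodes, dtype=int), :]
    flat = stack.reshape(stack.shape[0], -1)
    Z = linkage(flat, method="average", metric="euclidean")
    return {"labels": labels, "linkage": Z, "newick": _to_newick(Z, labels)}


def _to_newick(Z: np.ndarray, labels: list) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + k] = h
    return node[n + len(Z) - 1] + ";"
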