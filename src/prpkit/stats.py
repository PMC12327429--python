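"""Statistical layer: separability curves, cluster-mass permutation tests,
group tests, score transforms, and backward stepwise regression.

The cluster-mass permutation test controls the family-wise error of
mass-univariate t maps: electrodes (or time points) whose t value exceeds
the threshold equivalent to uncorrected p <= 0.05 are joined into connected
clusters under a declared adjacency, each cluster's mass is its summed t,
and corrected p values come from the maximum-mass null distribution over
permutations (sign flips for one-sample designs, label exchanges for
independent designs).  The largest absolute t in a cluster (t_max) is
reported as an effect-size estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components


# --------------------------------------------------------------------- F curve

@dataclass
class SeparabilityCurve:
    """Between- vs within-phoneme variability of PRPs over time."""

    time_s: np.ndarray
    f: np.ndarray                       # NaN where undefined
    undefined: np.ndarray


def separability_f(prp_sets: list) -> SeparabilityCurve:
    """One-way between/within mean-square ratio per time step.

    At each time step and electrode, phonemes are the groups and
    participants the replicates; the per-electrode ratios are averaged into
    F(t).  Points with zero within-phoneme variance are flagged undefined,
    not silently zeroed.
    """
    labels = sorted(set.intersection(*(set(s.prps) for s in prp_sets)))
    n_sub = len(prp_sets)
    if n_sub < 2:
        raise ValueError("need at least 2 participants per phoneme")
    data = np.stack([s.stack(labels) for s in prp_sets])   # (S, K, E, T)
    S, K, E, T = data.shape
    grand = data.mean(axis=(0, 1))                          # (E, T)
    group_mean = data.mean(axis=0)                          # (K, E, T)
    ms_between = S * ((group_mean - grand[None]) ** 2).sum(axis=0) / (K - 1)
    ms_within = ((data - group_mean[None]) ** 2).sum(axis=(0, 1)) / (K * (S - 1))
    undefined = ms_within == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, ms_between / ms_within)
    f = np.full(T, np.nan)
    col_ok = ~np.all(undefined, axis=0)
    f[col_ok] = np.nanmean(ratio[:, col_ok], axis=0)
    fs = prp_sets[0].fs
    return SeparabilityCurve(time_s=np.arange(T) / fs, f=f,
                             undefined=np.all(undefined, axis=0))


# ------------------------------------------------------------------ adjacency

def layout_adjacency(layout: np.ndarray, factor: float = 1.5) -> sparse.csr_matrix:
    """Neighbors = electrodes within ``factor`` x median nearest-neighbor
    distance on the 2D layout."""
    d = np.sqrt(((layout[:, None, :] - layout[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    thresh = factor * np.median(d.min(axis=1))
    adj = (d <= thresh)
    return sparse.csr_matrix(adj)


def chain_adjacency(n: int) -> sparse.csr_matrix:
    """1D adjacency for time-resolved curves (each sample touches neighbors)."""
    return sparse.csr_matrix(
        sparse.diags([1.0, 1.0], [-1, 1], shape=(n, n)) > 0)


# ----------------------------------------------------- cluster permutation test

@dataclass
class ClusterResult:
    clusters: list                      # list of dicts: members, sign, mass, t_max, p
    t_values: np.ndarray
    threshold: float
    n_perm: int
    seed: int

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["p"] < alpha]

    def significant_members(self, alpha: float = 0.05) -> np.ndarray:
        mem = sorted(set().union(*(set(c["members"])
                                   for c in self.significant(alpha))) or set())
        return np.asarray(mem, dtype=int)


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = x.mean(axis=0) / (sd / np.sqrt(n))
    return np.nan_to_num(t)


def _independent_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    nx, ny = x.shape[0], y.shape[0]
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x.mean(axis=0) - y.mean(axis=0)) / np.sqrt(
            pooled * (1 / nx + 1 / ny))
    return np.nan_to_num(t)


def _clusters_from_t(t: np.ndarray, thresh: float, adjacency, one_tailed: bool):
    """Connected same-sign supra-threshold clusters and their masses."""
    out = []
    signs = (1,) if one_tailed else (1, -1)
    for sign in signs:
        mask = (sign * t) > thresh
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, comp = connected_components(sub, directed=False)
        for ci in range(n_comp):
            members = idx[comp == ci]
            tm = t[members]
            out.append({"members": members.tolist(), "sign": sign,
                        "mass": float(tm.sum()),
                        "t_max": float(tm[np.argmax(np.abs(tm))])})
    return out


def cluster_permutation_test(topographies, design: str = "one-sample",
                             adjacency=None, n_perm: int = 10000,
                             seed: int = 0, p_threshold: float = 0.05,
                             smoothing: bool = False) -> ClusterResult:
    """Cluster-mass permutation test over electrodes (or time points).

    Parameters
    ----------
    topographies : array or (array, array)
        One-sample design: (n_subjects, n_positions) tested against zero,
        one-tailed (positive).  Independent design: a pair of such arrays,
        two-tailed.
    adjacency : sparse matrix
        Neighborhood structure; disconnected components trigger a warning.
    smoothing : bool
        If True, p = (1 + #null >= mass) / (1 + n_perm) instead of the plain
        proportion.
    """
    rng = np.random.default_rng(seed)
    if design == "one-sample":
        x = np.asarray(topographies, dtype=float)
        n, m = x.shape
        if n < 4:
            raise ValueError("need at least 4 participants")
        df = n - 1
        thresh = stats.t.ppf(1 - p_threshold, df)       # one-tailed
        t_obs = _one_sample_t(x)
        one_tailed = True
    elif design == "independent":
        x, y = (np.asarray(a, dtype=float) for a in topographies)
        if min(x.shape[0], y.shape[0]) < 4:
            raise ValueError("need at least 4 participants per group")
        m = x.shape[1]
        df = x.shape[0] + y.shape[0] - 2
        thresh = stats.t.ppf(1 - p_threshold / 2, df)   # two-tailed
        t_obs = _independent_t(x, y)
        one_tailed = False
    else:
        raise ValueError(f"unknown design {design!r}")

    if adjacency is None:
        adjacency = sparse.csr_matrix(np.ones((m, m), dtype=bool))
    n_comp, _ = connected_components(adjacency, directed=False)
    if n_comp > 1:
        warnings.warn(f"adjacency has {n_comp} disconnected components")

    clusters = _clusters_from_t(t_obs, thresh, adjacency, one_tailed)
    null_max = np.zeros(n_perm)
    if design == "one-sample":
        for i in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=x.shape[0])
            tp = _one_sample_t(x * flips[:, None])
            cs = _clusters_from_t(tp, thresh, adjacency, one_tailed)
            null_max[i] = max((abs(c["mass"]) for c in cs), default=0.0)
    else:
        pooled = np.vstack([x, y])
        nx = x.shape[0]
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            tp = _independent_t(pooled[perm[:nx]], pooled[perm[nx:]])
            cs = _clusters_from_t(tp, thresh, adjacency, one_tailed)
            null_max[i] = max((abs(c["mass"]) for c in cs), default=0.0)
    for c in clusters:
        exceed = int(np.sum(null_max >= abs(c["mass"])))
        c["p"] = ((1 + exceed) / (1 + n_perm)) if smoothing else exceed / n_perm
    clusters.sort(key=lambda c: c["p"])
    return ClusterResult(clusters=clusters, t_values=t_obs, threshold=thresh,
                         n_perm=n_perm, seed=seed)


# ------------------------------------------------------------------ group tests

def group_tests(values_a, values_b, kind: str = "welch") -> dict:
    """Welch's t test or Mann-Whitney U between two independent samples.

    Welch reports Satterthwaite df, Cohen's d (pooled SD) and the 95% CI of
    the mean difference; Mann-Whitney reports U and the tie-corrected normal
    approximation z (no continuity correction).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs n >= 2")
    degenerate = np.allclose(a, a[0]) and np.allclose(b, b[0]) \
        and np.isclose(a[0], b[0])
    if kind == "welch":
        if degenerate:
            return {"kind": "welch", "statistic": 0.0, "p": 1.0, "df": np.nan,
                    "cohen_d": 0.0, "ci95": (0.0, 0.0), "degenerate": True}
        res = stats.ttest_ind(a, b, equal_var=False)
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / na + vb / nb)
        df = se ** 4 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        tcrit = stats.t.ppf(0.975, df)
        diff = a.mean() - b.mean()
        return {"kind": "welch", "statistic": float(res.statistic),
                "p": float(res.pvalue), "df": float(df), "cohen_d": float(d),
                "ci95": (float(diff - tcrit * se), float(diff + tcrit * se)),
                "degenerate": False}
    if kind == "mann_whitney":
        if degenerate:
            return {"kind": "mann_whitney", "statistic": a.size * b.size / 2,
                    "p": 1.0, "z": 0.0, "degenerate": True}
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        u = float(res.statistic)
        na, nb = a.size, b.size
        mu = na * nb / 2.0
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = na + nb
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
        sigma = np.sqrt(na * nb / 12.0 * ((n + 1) - tie_term))
        z = (u - mu) / sigma if sigma > 0 else 0.0
        return {"kind": "mann_whitney", "statistic": u, "p": float(res.pvalue),
                "z": float(z), "degenerate": False}
    raise ValueError(f"unknown test kind {kind!r}")


# ------------------------------------------------------------------ transforms

def rau(correct: int, total: int) -> float:
    """Rationalized arcsine units: a linearized arcsine transform of
    proportion-correct scores that stabilizes variance near floor/ceiling.

    ``(146/pi) * [asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1)))] - 23``;
    maps n/2 of n to exactly 50.
    """
    if total < 1 or not 0 <= correct <= total:
        raise ValueError(f"need 0 <= correct <= total, total >= 1 "
                         f"(got {correct}/{total})")
    x, n = float(correct), float(total)
    theta = np.arcsin(np.sqrt(x / (n + 1))) + np.arcsin(np.sqrt((x + 1) / (n + 1)))
    return float(146.0 / np.pi * theta - 23.0)


def snr_loss(n_correct: int) -> float:
    """Words-in-noise SNR loss (dB): 26 - 0.4 * n for n of 70 correct."""
    if not 0 <= n_correct <= 70:
        raise ValueError(f"n_correct must be in [0, 70] (got {n_correct})")
    return 26.0 - 0.4 * n_correct


def ehf_transform(threshold_db_hl: float) -> float:
    """Normality transform for extended-high-frequency thresholds:
    natural log of (threshold + 25)."""
    if threshold_db_hl <= -25:
        raise ValueError("threshold must exceed -25 dB HL")
    return float(np.log(threshold_db_hl + 25.0))


# ---------------------------------------------------------- stepwise regression

@dataclass
class StepwiseResult:
    selected: list
    coefficients: pd.DataFrame          # beta, se, t, p per term
    aic: float
    adj_r2: float
    trace: list                         # [(predictor_removed, aic_after), ...]
    model: object = field(repr=False, default=None)
    zscale: dict = field(default=None, repr=False)


def _aic(n: int, rss: float, k_slopes: int) -> float:
    # Gaussian-likelihood AIC without the 2*pi constant; only differences matter
    return n * np.log(rss / n) + 2 * (k_slopes + 1)


def _fit_ols(y, X):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return model


def backward_stepwise(outcome, predictors: pd.DataFrame) -> StepwiseResult:
    """Backward AIC selection over z-scored predictors.

    Starts from the full ordinary-least-squares model and repeatedly removes
    the single predictor whose removal lowers the AIC most, stopping when no
    removal lowers it.  Missing values are dropped listwise first.
    """
    df = predictors.copy()
    df["__y"] = np.asarray(outcome, dtype=float)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        warnings.warn(f"listwise deletion dropped {n_before - len(df)} rows")
    y = df.pop("__y").to_numpy()
    names = list(df.columns)
    if len(df) < len(names) + 3:
        raise ValueError("need n >= number of predictors + 3")
    X = df.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant predictor(s): {bad}")
    zscale = {"mean": X.mean(axis=0), "sd": sds, "names": names}
    Xz = (X - zscale["mean"]) / sds
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xz])) < len(names) + 1:
        raise ValueError(f"rank-deficient predictor table: {names}")

    current = list(range(len(names)))
    model = _fit_ols(y, Xz[:, current])
    aic = _aic(len(y), float(model.ssr), len(current))
    trace = [(None, aic)]
    while current:
        best_drop, best_aic = None, aic
        for j in current:
            trial = [c for c in current if c != j]
            m = _fit_ols(y, Xz[:, trial]) if trial else _fit_ols(
                y, np.empty((len(y), 0)))
            a = _aic(len(y), float(m.ssr), len(trial))
            if a < best_aic - 1e-12:
                best_drop, best_aic = j, a
        if best_drop is None:
            break
        current = [c for c in current if c != best_drop]
        aic = best_aic
        trace.append((names[best_drop], aic))
    model = _fit_ols(y, Xz[:, current])
    terms = ["intercept"] + [names[c] for c in current]
    coef = pd.DataFrame({
        "term": terms, "beta": model.params, "se": model.bse,
        "t": model.tvalues, "p": model.pvalues}).reset_index(drop=True)
    return StepwiseResult(selected=[names[c] for c in current],
                          coefficients=coef, aic=aic,
                          adj_r2=float(model.rsquared_adj) if current else 0.0,
                          trace=trace, model=model, zscale=zscale)


def residual_group_test(outcome, predictors: pd.DataFrame, groups) -> dict:
    """Welch test on residuals of the pooled selected-predictor model.

    Fits OLS of the outcome on the (z-scored) predictors over all
    participants pooled, extracts residuals, and compares them between the
    two groups — the age-contrast-after-covariates analysis.
    """
    X = predictors.to_numpy(dtype=float)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    model = _fit_ols(np.asarray(outcome, dtype=float), Xz)
    resid = model.resid
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    res = group_tests(resid[groups == names[0]], resid[groups == names[1]],
                      kind="welch")
    res["groups"] = names.tolist()
    res["residuals"] = resid
    return res
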