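"""End-to-end orchestration: simulate → PRP → decode → relevance → RSA →
tracking → statistics, with seed management and a machine-readable report.

Each stage is a pure function of its inputs and the run seed; re-running a
stage with unchanged inputs reproduces its outputs.  The run report records
the configuration snapshot, per-stage output paths, and headline metrics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, relevance as rel, rsa, stats as st, tracking as trk
from .decoder import ClassifierSpec, desk_spec, repeat_protocol, frequency_accuracy_check
from .features import make_inventory
from .prp import extract_prps, preprocess_session, select_phonemes
from .session_io import write_session
from .simulate import CohortConfig, GroupParams, default_covariates, desk_config, \
    paper_scale_config, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prp", "decode", "relevance", "rsa", "track", "stats")
_DEPS = {"prp": {"simulate"}, "decode": {"prp"}, "relevance": {"decode"},
         "rsa": {"relevance"}, "track": {"prp"}, "stats": {"decode"}}


@dataclass
class RunSettings:
    """Tunable stage parameters beyond the cohort configuration."""

    spec: ClassifierSpec = field(default_factory=desk_spec)
    n_repeats: int = 3
    n_perm: int = 500
    rsa_window: tuple = (0.0, 0.35)
    trf_max_steps: int = 120
    trf_patience: int = 8
    prp_cap: int = 319
    min_fraction: float = 0.01
    exclude: tuple = ()


def load_config(path) -> tuple:
    """Read a plain-text key-value (YAML) run configuration.

    Recognized top-level keys: ``cohort`` (CohortConfig fields, with
    ``groups`` mapping and ``inventory: {n_phonemes, zipf_exponent, seed}``),
    ``decode`` (ClassifierSpec fields), ``n_repeats``, ``n_perm``,
    ``trf_max_steps``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    c = raw.get("cohort", {})
    groups = {name: GroupParams(**gp) for name, gp in c.pop("groups", {
        "A": {"alpha": 1.2, "sigma": 0.25},
        "B": {"alpha": 0.4, "sigma": 1.0, "tau_ms": 80.0}}).items()}
    inv = c.pop("inventory", {"n_phonemes": 12, "zipf_exponent": 0.7, "seed": 7})
    cohort = CohortConfig(
        n_per_group=c.pop("n_per_group", 10), group_params=groups,
        inventory=make_inventory(inv["n_phonemes"],
                                 inv.get("zipf_exponent", 1.0),
                                 inv.get("seed", 7)),
        covariate_specs=default_covariates(), **c)
    settings = RunSettings(
        spec=ClassifierSpec(**{**asdict(desk_spec()), **raw.get("decode", {})}),
        n_repeats=raw.get("n_repeats", 3), n_perm=raw.get("n_perm", 500),
        trf_max_steps=raw.get("trf_max_steps", 120))
    return cohort, settings


def preset_config(preset: str, seed: int) -> tuple:
    if preset == "desk":
        return desk_config(seed=seed), RunSettings()
    if preset == "paper":
        return paper_scale_config(seed=seed), RunSettings(
            spec=ClassifierSpec(), n_repeats=20, n_perm=10000)
    raise ValueError(f"unknown preset {preset!r}")


def _resolve_stages(stages) -> list:
    want = set(stages or STAGES)
    unknown = want - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for s in sorted(want):
        missing = _DEPS.get(s, set()) - want
        if missing:
            raise ValueError(
                f"stage {s!r} requires {sorted(missing)}; run those first "
                "or add them to --stages")
    return [s for s in STAGES if s in want]


def run_pipeline(cohort: CohortConfig, out_dir, stages=None,
                 settings: RunSettings | None = None,
                 write_sessions: bool = False) -> dict:
    """Execute the requested stages in dependency order; return the report."""
    settings = settings or RunSettings()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = _resolve_stages(stages)
    report = {"schema": "prpkit-report-v1", "version": __version__,
              "seed": cohort.seed, "stages": {}, "metrics": {},
              "config": {"n_per_group": cohort.n_per_group,
                         "n_electrodes": cohort.n_electrodes,
                         "fs": cohort.fs,
                         "groups": {g: asdict(gp) for g, gp
                                    in cohort.group_params.items()},
                         "n_phonemes": len(cohort.inventory.labels),
                         "noise_sd": cohort.noise_sd}}
    ctx = {}

    for stage in order:
        t0 = time.time()
        _STAGE_FN[stage](cohort, settings, out, ctx, report)
        report["stages"][stage] = {
            "wall_time_s": round(time.time() - t0, 2),
            "outputs": report["stages"].get(stage, {}).get("outputs", [])}
        logger.info("stage %s done in %.1f s", stage,
                    report["stages"][stage]["wall_time_s"])

    if write_sessions and "sessions" in ctx:
        for s in ctx["sessions"]:
            write_session(s, out / "sessions" / s.participant_id)
    (out / "report.json").write_text(json.dumps(_json_safe(report), indent=1))
    return report


def _json_safe(o):
    if isinstance(o, dict):
        return {str(k): _json_safe(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_json_safe(v) for v in o]
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    return o


# ------------------------------------------------------------------- stages

def _stage_simulate(cohort, settings, out, ctx, report):
    ctx["sessions"] = simulate_cohort(cohort)
    report["metrics"]["n_sessions"] = len(ctx["sessions"])


def _stage_prp(cohort, settings, out, ctx, report):
    clean, groups = {}, {}
    retained_all = None
    for s in ctx["sessions"]:
        rec, _ = preprocess_session(s)
        clean[s.participant_id] = rec
        retained = select_phonemes(s.annotations, settings.min_fraction,
                                   set(settings.exclude))
        retained_all = retained if retained_all is None else \
            sorted(set(retained_all) & set(retained))
    for s in ctx["sessions"]:
        ps = extract_prps(clean[s.participant_id], s.fs, s.annotations,
                          retained_all, cap=settings.prp_cap,
                          seed=cohort.seed, participant_id=s.participant_id,
                          group=s.group)
        groups.setdefault(s.group, []).append(ps)
    ctx["clean"] = clean
    ctx["prp_groups"] = groups
    ctx["retained"] = retained_all
    report["metrics"]["retained_phonemes"] = retained_all


def _stage_decode(cohort, settings, out, ctx, report):
    sessions = {s.participant_id: s for s in ctx["sessions"]}

    def resampler(group, prp_set, seed):
        s = sessions[prp_set.participant_id]
        return extract_prps(ctx["clean"][s.participant_id], s.fs,
                            s.annotations, ctx["retained"],
                            cap=settings.prp_cap, seed=seed,
                            participant_id=s.participant_id, group=s.group)

    res = repeat_protocol(ctx["prp_groups"], settings.spec,
                          n_repeats=settings.n_repeats,
                          root_seed=cohort.seed, resampler=resampler,
                          return_models=True)
    ctx["decode"] = res
    outputs = []
    for g, tab in res["per_participant"].items():
        p = out / f"decode_{g}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        with open(out / f"decode_records_{g}.jsonl", "w") as fh:
            for cv in res["cv_results"][g]:
                for rec in cv.records.to_dict("records"):
                    rec["repetition"] = cv.repetition
                    fh.write(json.dumps(rec) + "\n")
        report["metrics"][f"accuracy_{g}"] = float(tab["accuracy"].mean())
        report["metrics"][f"entropy_{g}"] = float(tab["entropy"].mean())
        labels = res["cv_results"][g][0].labels
        pd.DataFrame(res["confusion"][g], index=labels, columns=labels) \
            .to_csv(out / f"confusion_{g}.csv")
    freq = dict(zip(cohort.inventory.labels, cohort.inventory.weights))
    fac = frequency_accuracy_check(
        list(ctx["decode"]["cv_results"].values())[0][0], freq)
    report["metrics"]["freq_accuracy_r"] = fac["r"]
    report["metrics"]["freq_accuracy_p"] = fac["p"]
    report["metrics"]["chance_level"] = 1.0 / len(ctx["retained"])
    report["stages"].setdefault("decode", {})["outputs"] = outputs


def _stage_relevance(cohort, settings, out, ctx, report):
    maps = {}
    for g, cvs in ctx["decode"]["cv_results"].items():
        maps[g] = []
        for pid in sorted({p for cv in cvs
                           for p in cv.records["participant"].unique()}):
            per_rep = []
            for rep, cv in enumerate(cvs):
                if pid in set(cv.records["participant"]):
                    per_rep.append(rel.relevance_map(
                        cv, ctx["decode"]["prp_sets"][g][rep], pid))
            per_rep = [m for m in per_rep if m is not None]
            if per_rep:
                maps[g].append(rel.average_maps(per_rep))
    ctx["relevance"] = maps
    rows = []
    map_dir = out / "relevance_maps"
    map_dir.mkdir(exist_ok=True)
    for g, ms in maps.items():
        for m in ms:
            pd.DataFrame(m.scores).to_csv(map_dir / f"{m.participant_id}.csv",
                                          index=False)
            rows.append({"participant": m.participant_id, "group": g,
                         "dispersion": rel.dispersion(m),
                         "peak_latency_ms": rel.peak_latency(m)[0]})
    tab = pd.DataFrame(rows)
    tab.to_csv(out / "relevance.tsv", sep="\t", index=False)
    for g in maps:
        report["metrics"][f"dispersion_{g}"] = float(
            tab.loc[tab.group == g, "dispersion"].mean())
        report["metrics"][f"peak_latency_ms_{g}"] = float(
            tab.loc[tab.group == g, "peak_latency_ms"].median())
    report["stages"].setdefault("relevance", {})["outputs"] = [
        str(out / "relevance.tsv")]


def _stage_rsa(cohort, settings, out, ctx, report):
    feature = rsa.feature_rdm(_retained_table(cohort, ctx["retained"]))
    ctx["feature_rdm"] = feature
    sel, curves = {}, {}
    for g, prp_sets in ctx["prp_groups"].items():
        ranking = rel.electrode_ranking(ctx["relevance"][g])
        electrodes, best, _ = rsa.forward_select(prp_sets, ranking, feature)
        sel[g] = electrodes
        curves[g] = np.vstack([
            rsa.alignment(rsa.neural_rdm_series(s, electrodes), feature,
                          fs=s.fs).rho
            for s in prp_sets])
        report["metrics"][f"rsa_electrodes_{g}"] = electrodes.tolist()
        report["metrics"][f"rsa_overall_rho_{g}"] = best
    ctx["rsa_curves"] = curves
    names = list(curves)
    T = curves[names[0]].shape[1]
    cl = st.cluster_permutation_test(
        (curves[names[0]], curves[names[1]]), design="independent",
        adjacency=st.chain_adjacency(T), n_perm=settings.n_perm,
        seed=cohort.seed)
    report["metrics"]["rsa_curve_clusters"] = [
        {"p": c["p"], "t_max": c["t_max"]} for c in cl.clusters[:3]]
    conf = ctx["decode"]["confusion"]
    perm = rsa.permutation_rho_difference(conf[names[0]], conf[names[1]],
                                          feature, n_perm=settings.n_perm,
                                          seed=cohort.seed)
    report["metrics"]["confusion_rho"] = {
        names[0]: rsa.rho_of_confusion(conf[names[0]], feature),
        names[1]: rsa.rho_of_confusion(conf[names[1]], feature)}
    report["metrics"]["confusion_rho_diff_p"] = perm["p"]
    outputs = []
    for g, prp_sets in ctx["prp_groups"].items():
        mean_set = _group_mean_prpset(prp_sets)
        dend = rsa.phoneme_dendrogram(mean_set, electrodes=sel[g],
                                      window=settings.rsa_window)
        p = out / f"dendrogram_{g}.nwk"
        p.write_text(dend["newick"] + "\n")
        outputs.append(str(p))
        pd.DataFrame(curves[g]).to_csv(out / f"alignment_{g}.tsv", sep="\t",
                                       index=False)
    report["stages"].setdefault("rsa", {})["outputs"] = outputs


def _stage_track(cohort, settings, out, ctx, report):
    rows, dr_env, dr_on = [], [], []
    for s in ctx["sessions"]:
        ps = trk.derive_predictors(band_envelopes=s.predictors[:trk.N_BANDS],
                                   fs_eeg=s.fs)
        eeg = ctx["clean"][s.participant_id]
        models = {}
        for fam in ("both", "envelope", "onset"):
            X, names = ps.stack(fam)
            models[fam] = trk.boost_trf(
                X, eeg, s.fs, s.segment_bounds, seed=cohort.seed,
                max_steps=settings.trf_max_steps,
                patience=settings.trf_patience, predictor_names=names)
        dr_env.append(trk.delta_r(models["both"], models["onset"]))
        dr_on.append(trk.delta_r(models["both"], models["envelope"]))
        rows.append({"participant": s.participant_id, "group": s.group,
                     "r_full_mean": float(models["both"].r.mean())})
    adjacency = st.layout_adjacency(cohort.layout)
    ctx["track"] = {}
    for fam, mat in (("envelope", np.vstack(dr_env)), ("onset", np.vstack(dr_on))):
        roi = trk.roi_score(mat, adjacency=adjacency, n_perm=settings.n_perm,
                            seed=cohort.seed)
        ctx["track"][fam] = {"delta_r": mat, "roi": roi}
        report["metrics"][f"roi_{fam}"] = roi["roi"].tolist()
        report["metrics"][f"tracking_score_{fam}"] = (
            float(np.nanmean(roi["scores"])) if roi["roi"].size else None)
    tab = pd.DataFrame(rows)
    tab.to_csv(out / "tracking.tsv", sep="\t", index=False)
    ctx["track"]["participants"] = [s.participant_id for s in ctx["sessions"]]
    ctx["track"]["groups"] = [s.group for s in ctx["sessions"]]
    report["stages"].setdefault("track", {})["outputs"] = [
        str(out / "tracking.tsv")]


def _stage_stats(cohort, settings, out, ctx, report):
    results = {}
    names = list(ctx["prp_groups"])
    # PRP separability curve per group
    for g, prp_sets in ctx["prp_groups"].items():
        curve = st.separability_f(prp_sets)
        results[f"f_curve_mean_{g}"] = float(np.nanmean(curve.f))
    # group tests on decoding metrics
    pp = ctx["decode"]["per_participant"]
    a, b = pp[names[0]], pp[names[1]]
    results["accuracy_test"] = st.group_tests(a["accuracy"], b["accuracy"],
                                              kind="mann_whitney")
    results["entropy_test"] = st.group_tests(a["entropy"], b["entropy"],
                                             kind="mann_whitney")
    if "relevance" in ctx:
        disp = {g: [rel.dispersion(m) for m in ms]
                for g, ms in ctx["relevance"].items()}
        lat = {g: [rel.peak_latency(m)[0] for m in ms]
               for g, ms in ctx["relevance"].items()}
        results["dispersion_test"] = st.group_tests(
            disp[names[0]], disp[names[1]], kind="welch")
        results["latency_test"] = st.group_tests(
            lat[names[0]], lat[names[1]], kind="mann_whitney")
        topo = {g: np.vstack([m.scores.mean(axis=1) for m in ms])
                for g, ms in ctx["relevance"].items()}
        cl = st.cluster_permutation_test(
            (topo[names[0]], topo[names[1]]), design="independent",
            adjacency=st.layout_adjacency(cohort.layout),
            n_perm=settings.n_perm, seed=cohort.seed)
        results["relevance_topography_clusters"] = [
            {"p": c["p"], "t_max": c["t_max"], "members": c["members"]}
            for c in cl.clusters[:5]]
    # covariate regression on RAU-transformed accuracy
    sessions = {s.participant_id: s for s in ctx["sessions"]}
    recs = []
    for g in names:
        for _, row in pp[g].iterrows():
            cov = dict(sessions[row["participant"]].covariates)
            if "ehf_threshold" in cov:
                cov["ehf_threshold"] = st.ehf_transform(
                    max(cov["ehf_threshold"], -24.0))
            n_samples = len(ctx["retained"])
            correct = int(round(row["accuracy"] * n_samples))
            recs.append({"participant": row["participant"], "group": g,
                         "rau_acc": st.rau(correct, n_samples), **cov})
    tab = pd.DataFrame(recs)
    predictors = tab.drop(columns=["participant", "group", "rau_acc"])
    try:
        sw = st.backward_stepwise(tab["rau_acc"], predictors)
        results["stepwise_selected"] = sw.selected
        results["stepwise_aic"] = sw.aic
        results["stepwise_adj_r2"] = sw.adj_r2
        if sw.selected:
            rg = st.residual_group_test(tab["rau_acc"], predictors[sw.selected],
                                        tab["group"])
            results["residual_test"] = {k: rg[k] for k in
                                        ("statistic", "p", "df", "cohen_d")}
    except ValueError as e:
        results["stepwise_error"] = str(e)
    report["metrics"]["stats"] = _json_safe(
        {k: (v if not isinstance(v, dict) else
             {kk: vv for kk, vv in v.items() if kk != "residuals"})
         for k, v in results.items()})
    p = out / "stats.json"
    p.write_text(json.dumps(_json_safe(report["metrics"]["stats"]), indent=1))
    report["stages"].setdefault("stats", {})["outputs"] = [str(p)]


def _retained_table(cohort, retained):
    inv = cohort.inventory
    w = np.array([inv.weights[list(inv.labels).index(lab)] for lab in retained])
    from .features import PhonemeFeatureTable
    return PhonemeFeatureTable(labels=tuple(retained),
                               features={lab: inv.features[lab]
                                         for lab in retained},
                               weights=w / w.sum())


def _group_mean_prpset(prp_sets):
    from .prp import PRPSet
    labels = sorted(set.intersection(*(set(s.prps) for s in prp_sets)))
    prps = {lab: np.mean([s.prps[lab] for s in prp_sets], axis=0)
            for lab in labels}
    first = prp_sets[0]
    return PRPSet(participant_id=f"mean-{first.group}", group=first.group,
                  fs=first.fs, window=first.window, prps=prps,
                  counts={lab: len(prp_sets) for lab in labels})


_STAGE_FN = {"simulate": _stage_simulate, "prp": _stage_prp,
             "decode": _stage_decode, "relevance": _stage_relevance,
             "rsa": _stage_rsa, "track": _stage_track, "stats": _stage_stats}
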