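"""On-disk formats for simulated sessions and analysis products.

A session directory holds:

* ``recording.bin``  — float32 little-endian channel-major matrix (raw
  binary; the companion header documents the layout)
* ``recording.json`` — header sidecar: channel names, fs, shape, dtype,
  byte order, segment boundaries
* ``annotations.csv`` — UTF-8 CSV with header ``onset_s,duration_s,phoneme``
* ``predictors.csv``  — 16 columns (8 band envelopes + 8 band onsets) at the
  EEG rate
* ``covariates.json`` / ``truth.json`` — scalar covariates and the
  generative truth block (templates and kernels as nested lists)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimulatedSession


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_session(session: SimulatedSession, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = np.ascontiguousarray(session.recording, dtype="<f4")
    (out / "recording.bin").write_bytes(rec.tobytes())
    header = {
        "format": "prpkit-raw-v1",
        "dtype": "float32", "byte_order": "little", "order": "channel-major",
        "shape": list(rec.shape), "fs": session.fs,
        "ch_names": session.ch_names, "units": "uV",
        "participant_id": session.participant_id, "group": session.group,
        "segment_bounds": [list(b) for b in session.segment_bounds],
    }
    (out / "recording.json").write_text(json.dumps(header, indent=1))
    session.annotations.to_csv(out / "annotations.csv", index=False)
    pd.DataFrame(session.predictors.T, columns=session.predictor_names).to_csv(
        out / "predictors.csv", index=False)
    (out / "covariates.json").write_text(
        json.dumps(_jsonable(session.covariates), indent=1))
    (out / "truth.json").write_text(json.dumps(_jsonable(session.truth)))
    return out


def write_prpset(prp_set, path_stem) -> Path:
    """Serialize a PRPSet as raw float32 binary + JSON header.

    The binary holds the (K, E, T) stack in sorted-label order; the header
    records labels, counts, window, fs and the array layout.
    """
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    stack = np.ascontiguousarray(prp_set.stack(), dtype="<f4")
    stem.with_suffix(".bin").write_bytes(stack.tobytes())
    header = {
        "format": "prpkit-prpset-v1", "dtype": "float32",
        "byte_order": "little", "shape": list(stack.shape),
        "labels": prp_set.labels, "counts": prp_set.counts,
        "window": list(prp_set.window), "fs": prp_set.fs,
        "participant_id": prp_set.participant_id, "group": prp_set.group,
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return stem


def read_prpset(path_stem):
    from .prp import PRPSet
    stem = Path(path_stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    stack = np.frombuffer(stem.with_suffix(".bin").read_bytes(),
                          dtype="<f4").reshape(header["shape"]).astype(float)
    prps = {lab: stack[i] for i, lab in enumerate(header["labels"])}
    return PRPSet(participant_id=header["participant_id"],
                  group=header["group"], fs=header["fs"],
                  window=tuple(header["window"]), prps=prps,
                  counts={k: int(v) for k, v in header["counts"].items()})


def write_trf(model, path_stem) -> Path:
    """Serialize TRF kernels (P, E, L) as raw float32 binary + JSON header."""
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    k = np.ascontiguousarray(model.kernels, dtype="<f4")
    stem.with_suffix(".bin").write_bytes(k.tobytes())
    header = {
        "format": "prpkit-trf-v1", "dtype": "float32",
        "byte_order": "little", "shape": list(k.shape),
        "lags_s": model.lags_s.tolist(), "r": model.r.tolist(),
        "predictor_names": model.predictor_names, "n_folds": model.n_folds,
    }
    stem.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return stem


def read_session(session_dir) -> SimulatedSession:
    d = Path(session_dir)
    header = json.loads((d / "recording.json").read_text())
    rec = np.frombuffer((d / "recording.bin").read_bytes(),
                        dtype="<f4").reshape(header["shape"]).astype(float)
    annotations = pd.read_csv(d / "annotations.csv")
    pred = pd.read_csv(d / "predictors.csv")
    covariates = json.loads((d / "covariates.json").read_text())
    truth = json.loads((d / "truth.json").read_text())
    truth["templates"] = {k: np.asarray(v)
                          for k, v in truth["templates"].items()}
    truth["kernels"] = np.asarray(truth["kernels"])
    truth["layout"] = np.asarray(truth["layout"])
    return SimulatedSession(
        participant_id=header["participant_id"], group=header["group"],
        fs=header["fs"], recording=rec, ch_names=header["ch_names"],
        annotations=annotations, predictors=pred.to_numpy().T,
        predictor_names=list(pred.columns),
        segment_bounds=[tuple(b) for b in header["segment_bounds"]],
        covariates=covariates, truth=truth)
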