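"""HDF5/CSV/JSON serialization of the pipeline's data objects."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hmm import HMMModel, StateSequence
from .synthetic import EnvelopeDataset


def write_envelope_dataset(path, dataset: EnvelopeDataset, **attrs) -> None:
    """HDF5 layout: /<subject>/<session>/envelope (nodes x time), attrs fs/band."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = dataset.fs
        f.attrs["band"] = list(dataset.band)
        for key, val in attrs.items():
            f.attrs[key] = val
        for subj, sess, env in dataset.recordings():
            f.create_group(f"{subj}/{sess}") if f"{subj}/{sess}" not in f else None
            f[f"{subj}/{sess}"].create_dataset("envelope", data=env)


def read_envelope_dataset(path) -> EnvelopeDataset:
    data = {}
    subjects, sessions = [], []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        band = tuple(f.attrs.get("band", (4.0, 30.0)))
        for subj in sorted(f.keys()):
            subjects.append(subj)
            for sess in sorted(f[subj].keys(), key=lambda s: (len(s), s)):
                if sess not in sessions:
                    sessions.append(sess)
                data[(subj, sess)] = f[subj][sess]["envelope"][()]
    return EnvelopeDataset(subjects=subjects, sessions=sessions, data=data, fs=fs, band=band)


def write_state_paths_json(path, paths: dict) -> None:
    payload = {f"{s}|{r}": np.asarray(p).tolist() for (s, r), p in paths.items()}
    Path(path).write_text(json.dumps(payload))


def read_state_paths_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {tuple(k.split("|")): np.asarray(v, dtype=np.int64) for k, v in payload.items()}


def write_hmm_model(path, model: HMMModel, **meta) -> None:
    payload = {
        "K": model.K,
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "means": model.means.tolist(),
        "covars": model.covars.tolist(),
        "score": model.score,
        "restart_index": model.restart_index,
        "covariance_type": model.covariance_type,
        "converged": model.converged,
        **meta,
    }
    Path(path).write_text(json.dumps(payload))


def read_hmm_model(path) -> HMMModel:
    d = json.loads(Path(path).read_text())
    return HMMModel(
        K=d["K"],
        startprob=np.asarray(d["startprob"]),
        transmat=np.asarray(d["transmat"]),
        means=np.asarray(d["means"]),
        covars=np.asarray(d["covars"]),
        score=d["score"],
        restart_index=d["restart_index"],
        covariance_type=d.get("covariance_type", "full"),
        converged=d.get("converged", True),
    )


def write_state_sequence(path, seq: StateSequence) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("path", data=seq.path)
        f.attrs["K"] = seq.K
        if seq.boundaries:
            rec = np.array(
                [(s, r, a, b) for (s, r, a, b) in seq.boundaries],
                dtype=[("subject", "S32"), ("session", "S16"), ("start", "i8"), ("end", "i8")],
            )
            f.create_dataset("boundaries", data=rec)


def read_state_sequence(path) -> StateSequence:
    with h5py.File(path, "r") as f:
        pathvec = f["path"][()]
        K = int(f.attrs["K"])
        bounds = []
        if "boundaries" in f:
            for row in f["boundaries"][()]:
                bounds.append(
                    (row["subject"].decode(), row["session"].decode(), int(row["start"]), int(row["end"]))
                )
    return StateSequence(path=pathvec, K=K, boundaries=bounds)


def write_connectomes(path, matrices: dict, powers: dict, band: str = "wide", **attrs) -> None:
    """HDF5: /<subject>/<session>/{matrix,power}, attrs band + extras."""
    with h5py.File(path, "w") as f:
        f.attrs["band"] = band
        for k, v in attrs.items():
            f.attrs[k] = v
        for (subj, sess), mat in matrices.items():
            g = f.require_group(f"{subj}/{sess}")
            g.create_dataset("matrix", data=mat)
            g.create_dataset("power", data=powers[(subj, sess)])


def read_connectomes(path) -> tuple[dict, dict, str]:
    matrices, powers = {}, {}
    with h5py.File(path, "r") as f:
        band = f.attrs.get("band", "wide")
        if isinstance(band, bytes):
            band = band.decode()
        for subj in f.keys():
            for sess in f[subj].keys():
                matrices[(subj, sess)] = f[subj][sess]["matrix"][()]
                powers[(subj, sess)] = f[subj][sess]["power"][()]
    return matrices, powers, str(band)


def write_nbs_result(path, result, registry: pd.DataFrame | None = None) -> None:
    names = registry["name"].tolist() if registry is not None else None
    payload = {
        "threshold": result.threshold,
        "tail": result.tail,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "components": [
            {
                "size": c.size,
                "p_fwer": c.p_fwer,
                "nodes": c.nodes,
                "node_names": [names[i] for i in c.nodes] if names else None,
                "edges": c.edges,
            }
            for c in result.components
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
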