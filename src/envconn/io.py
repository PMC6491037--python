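"""File formats: HDF5 containers for timeseries/envelopes/connectomes,
TSV for matrices and edge lists, JSON for reports.

HDF5 layout
-----------
* cohort file: one group per subject with ``data`` (nodes x samples),
  ``node_labels``, and ``sampling_rate``/``group`` attributes;
* envelope file: ``/<subject>/<band>`` datasets with ``rate`` and band
  edges as attributes;
* connectome file: ``/<subject>/<band>`` symmetric matrices.

Datasets are written with ``track_times=False`` so equal inputs produce
bitwise-equal files (checksummable run manifests).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .bands import BandSpec
from .connectome import ConnMatrix, EdgeMask
from .envelope import EnvelopeSet
from .synthetic import SubjectRecording

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_envelopes",
    "load_envelopes",
    "save_connectomes",
    "load_connectomes",
    "write_connectome_tsv",
    "read_connectome_tsv",
    "write_edge_mask_tsv",
    "read_edge_mask_tsv",
    "write_json",
]

_DSET_OPTS = dict(track_times=False)


def save_cohort(recordings: Sequence[SubjectRecording], path) -> None:
    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.create_group(rec.subject_id)
            g.create_dataset("data", data=rec.data, **_DSET_OPTS)
            g.create_dataset(
                "node_labels",
                data=np.array(rec.node_labels, dtype="S"),
                **_DSET_OPTS,
            )
            g.attrs["sampling_rate"] = rec.sampling_rate
            g.attrs["group"] = rec.group


def load_cohort(path) -> list[SubjectRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            out.append(
                SubjectRecording(
                    subject_id=sid,
                    group=g.attrs["group"],
                    data=g["data"][...],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    node_labels=[s.decode() for s in g["node_labels"][...]],
                )
            )
    return out


def save_envelopes(env_sets: Sequence[EnvelopeSet], path) -> None:
    with h5py.File(path, "w") as f:
        for es in env_sets:
            band = es.band.name if isinstance(es.band, BandSpec) else str(es.band)
            d = f.require_group(es.subject_id).create_dataset(
                band, data=es.env, **_DSET_OPTS
            )
            d.attrs["rate"] = es.rate
            if isinstance(es.band, BandSpec):
                d.attrs["f_low"] = es.band.f_low
                d.attrs["f_high"] = es.band.f_high


def load_envelopes(path) -> list[EnvelopeSet]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            for band_name in sorted(f[sid].keys()):
                d = f[sid][band_name]
                band = (
                    BandSpec(band_name, float(d.attrs["f_low"]), float(d.attrs["f_high"]))
                    if "f_low" in d.attrs
                    else band_name
                )
                out.append(
                    EnvelopeSet(
                        subject_id=sid, band=band, env=d[...], rate=float(d.attrs["rate"])
                    )
                )
    return out


def save_connectomes(conns: Sequence[ConnMatrix], path) -> None:
    with h5py.File(path, "w") as f:
        for c in conns:
            d = f.require_group(c.subject_id).create_dataset(
                c.band, data=c.z, **_DSET_OPTS
            )
            if c.node_labels:
                d.attrs["node_labels"] = np.array(c.node_labels, dtype="S")


def load_connectomes(path) -> list[ConnMatrix]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            for band in sorted(f[sid].keys()):
                d = f[sid][band]
                labels = (
                    [s.decode() for s in d.attrs["node_labels"]]
                    if "node_labels" in d.attrs
                    else None
                )
                out.append(
                    ConnMatrix(subject_id=sid, band=band, z=d[...], node_labels=labels)
                )
    return out


def write_connectome_tsv(conn: ConnMatrix, path) -> None:
    """Labelled TSV with header row/column; band and subject as comments."""
    labels = conn.node_labels or [f"node{k:03d}" for k in range(conn.n_nodes)]
    with open(path, "w") as f:
        f.write(f"# band: {conn.band}\n# subject: {conn.subject_id}\n")
        f.write("\t".join(["node"] + labels) + "\n")
        for lab, row in zip(labels, conn.z):
            f.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_connectome_tsv(path) -> ConnMatrix:
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty connectome file")
    band, subject = "unknown", path.stem
    rows, row_labels, col_labels = [], [], None
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "band":
                band = val.strip()
            elif key.strip() == "subject":
                subject = val.strip()
            continue
        parts = line.split("\t")
        if col_labels is None:
            col_labels = parts[1:]
            continue
        row_labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if col_labels is None or not rows:
        raise ValueError(f"{path}: no matrix data found")
    z = np.asarray(rows)
    if z.shape[0] != z.shape[1] or row_labels != col_labels:
        raise ValueError(f"{path}: row/column labels do not match")
    if np.any(~np.isfinite(z)):
        i, j = map(int, np.argwhere(~np.isfinite(z))[0])
        raise ValueError(f"{path}: non-finite value at ({row_labels[i]}, {col_labels[j]})")
    asym = np.abs(z - z.T)
    if asym.max() > 1e-10:
        i, j = map(int, np.unravel_index(np.argmax(asym), z.shape))
        raise ValueError(
            f"{path}: asymmetric entry at ({row_labels[i]}, {col_labels[j]}): "
            f"{z[i, j]} vs {z[j, i]}"
        )
    if np.any(np.diag(z) != 0):
        i = int(np.flatnonzero(np.diag(z))[0])
        raise ValueError(f"{path}: nonzero diagonal at {row_labels[i]}")
    return ConnMatrix(subject_id=subject, band=band, z=z, node_labels=list(row_labels))


def write_edge_mask_tsv(mask: EdgeMask, path, node_labels: Sequence[str] | None = None) -> None:
    """Two-column 0-based edge list (node_i < node_j), labels appended."""
    labels = list(node_labels) if node_labels else [f"node{k:03d}" for k in range(mask.n_nodes)]
    with open(path, "w") as f:
        f.write(f"# band: {mask.band}\n# scope: {mask.scope}\n# n_nodes: {mask.n_nodes}\n")
        f.write("node_i\tnode_j\tlabel_i\tlabel_j\n")
        for i, j in mask.edge_list():
            f.write(f"{i}\t{j}\t{labels[i]}\t{labels[j]}\n")


def read_edge_mask_tsv(path) -> EdgeMask:
    path = Path(path)
    band, scope, n_nodes = "unknown", "pooled", None
    edges = []
    lines = path.read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty edge-mask file")
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "band":
                band = val.strip()
            elif key == "scope":
                scope = val.strip()
            elif key == "n_nodes":
                n_nodes = int(val)
            continue
        if line.startswith("node_i"):
            continue
        parts = line.split("\t")
        edges.append((int(parts[0]), int(parts[1])))
    if n_nodes is None:
        raise ValueError(f"{path}: missing '# n_nodes:' header")
    m = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        m[i, j] = m[j, i] = True
    return EdgeMask(band=band, mask=m, scope=scope)


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
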