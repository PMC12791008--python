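"""Readers and writers for the package's plain-text and TIFF interchange formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .align import ConsensusTimeline, CorrespondenceCurve
from .grids import (
    FieldFrame,
    FieldSequence,
    GridSpec,
    StripeCurve,
    VelocityFrame,
    VelocitySequence,
)
from .kinematics import ModuleSegmentation, PathlineSet
from .shape3d import DeformationFrame, MeshSequence, TriMeshFrame
from .similarity import SimilarityMatrix

__all__ = [
    "write_field_sequence",
    "read_field_sequence",
    "write_velocity_sequence",
    "read_velocity_sequence",
    "write_stripe_curve",
    "read_stripe_curve",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_correspondence_curve",
    "read_correspondence_curve",
    "write_consensus_timeline",
    "read_consensus_timeline",
    "write_pathlines",
    "write_module_segmentation",
    "read_module_segmentation",
    "write_ply",
    "read_ply",
    "write_mesh_sequence",
    "read_mesh_sequence",
    "write_deformation_frame",
    "read_deformation_frame",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# -- scalar image sequences: multi-page float32 TIFF + JSON sidecar ---------


def write_field_sequence(seq: FieldSequence, path) -> None:
    path = Path(path)
    stack = np.stack([np.where(f.valid, f.values, np.nan) for f in seq]).astype(np.float32)
    tifffile.imwrite(path, stack)
    g = seq.grid
    meta = {
        "dt_min": seq.dt,
        "start_time_min": float(seq[0].time),
        "spacing1_um": g.spacing1,
        "spacing2_um": g.spacing2,
        "periodic2": g.periodic2,
        "truncation_fraction": g.truncation_fraction,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_field_sequence(path) -> FieldSequence:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(_sidecar(path).read_text())
    g = GridSpec(
        stack.shape[1],
        stack.shape[2],
        meta["spacing1_um"],
        meta["spacing2_um"],
        meta["periodic2"],
        meta.get("truncation_fraction", 0.08),
    )
    dt = meta["dt_min"]
    t0 = meta.get("start_time_min", 0.0)
    frames = [FieldFrame(g, a.astype(float), t0 + k * dt) for k, a in enumerate(stack)]
    return FieldSequence(frames, dt)


# -- velocity sequences: long-format CSV ------------------------------------


def write_velocity_sequence(seq: VelocitySequence, path) -> None:
    path = Path(path)
    rows = []
    for k, f in enumerate(seq):
        i1, i2 = np.meshgrid(np.arange(f.grid.n1), np.arange(f.grid.n2), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "frame": k,
                    "x1_idx": i1.ravel(),
                    "x2_idx": i2.ravel(),
                    "v1_um_per_min": f.v1.ravel(),
                    "v2_um_per_min": f.v2.ravel(),
                    "valid": f.valid.ravel().astype(int),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False)
    g = seq.grid
    meta = {
        "dt_min": seq.dt,
        "start_time_min": float(seq[0].time),
        "n1": g.n1,
        "n2": g.n2,
        "spacing1_um": g.spacing1,
        "spacing2_um": g.spacing2,
        "periodic2": g.periodic2,
        "truncation_fraction": g.truncation_fraction,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_velocity_sequence(path) -> VelocitySequence:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    g = GridSpec(
        meta["n1"],
        meta["n2"],
        meta["spacing1_um"],
        meta["spacing2_um"],
        meta["periodic2"],
        meta.get("truncation_fraction", 0.08),
    )
    dt, t0 = meta["dt_min"], meta.get("start_time_min", 0.0)
    frames = []
    for k, sub in df.groupby("frame"):
        v1 = np.full(g.shape, np.nan)
        v2 = np.full(g.shape, np.nan)
        ok = np.zeros(g.shape, dtype=bool)
        i1 = sub["x1_idx"].to_numpy()
        i2 = sub["x2_idx"].to_numpy()
        v1[i1, i2] = sub["v1_um_per_min"].to_numpy()
        v2[i1, i2] = sub["v2_um_per_min"].to_numpy()
        ok[i1, i2] = sub["valid"].to_numpy().astype(bool)
        frames.append(VelocityFrame(g, v1, v2, t0 + int(k) * dt, ok))
    return VelocitySequence(frames, dt)


# -- curves, matrices, correspondence ---------------------------------------


def write_stripe_curve(curve: StripeCurve, path) -> None:
    df = pd.DataFrame(
        {
            "point": np.arange(len(curve.points)),
            "x1_um": curve.points[:, 0],
            "x2_um": curve.points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_stripe_curve(path, closed2: bool = False) -> StripeCurve:
    df = pd.read_csv(path).sort_values("point")
    return StripeCurve(df[["x1_um", "x2_um"]].to_numpy(), closed2=closed2)


def write_similarity_matrix(m: SimilarityMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.times_a, columns=m.times_b)
    df.to_csv(path, index_label="t_a_min\\t_b_min")
    _sidecar(path).write_text(json.dumps({"measure_id": m.measure_id, "params": m.params}, indent=1))


def read_similarity_matrix(path) -> SimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return SimilarityMatrix(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
        meta.get("measure_id", ""),
        meta.get("params", {}),
    )


def write_correspondence_curve(c: CorrespondenceCurve, path) -> None:
    pd.DataFrame({"t_a_min": c.t_a, "t_b_min": c.t_b}).to_csv(path, index=False)


def read_correspondence_curve(path) -> CorrespondenceCurve:
    df = pd.read_csv(path)
    return CorrespondenceCurve(df["t_a_min"].to_numpy(), df["t_b_min"].to_numpy())


def write_consensus_timeline(tl: ConsensusTimeline, path) -> None:
    obj = {
        "dt": tl.dt,
        "medoid_id": tl.medoid_id,
        "member_ids": list(tl.member_ids),
        "maps": {
            str(i): {"t_member": c.t_a.tolist(), "t_consensus": c.t_b.tolist()}
            for i, c in tl.maps.items()
        },
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_consensus_timeline(path) -> ConsensusTimeline:
    obj = json.loads(Path(path).read_text())
    maps = {
        i: CorrespondenceCurve(np.asarray(m["t_member"]), np.asarray(m["t_consensus"]))
        for i, m in obj["maps"].items()
    }
    ids = [str(i) for i in obj["member_ids"]]
    return ConsensusTimeline(ids, maps, obj["dt"], obj.get("medoid_id"))


def write_pathlines(p: PathlineSet, path) -> None:
    n_seed, n_pos, _ = p.positions.shape
    seed_idx = np.repeat(np.arange(n_seed), n_pos)
    step = np.tile(np.arange(n_pos), n_seed)
    df = pd.DataFrame(
        {
            "seed": seed_idx,
            "step": step,
            "t_min": p.t_start + step * p.dt_int,
            "x1_um": p.positions[:, :, 0].ravel(),
            "x2_um": p.positions[:, :, 1].ravel(),
            "escaped": np.repeat(p.escaped.astype(int), n_pos),
        }
    )
    df.to_csv(path, index=False)


def write_module_segmentation(seg: ModuleSegmentation, path) -> None:
    obj = {
        "threshold": seg.threshold,
        "modules": [
            {"t_start": t0, "t_end": t1, "mean_correlation": mc, "label": lab}
            for t0, t1, mc, lab in seg.modules
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_module_segmentation(path) -> ModuleSegmentation:
    obj = json.loads(Path(path).read_text())
    mods = [
        (m["t_start"], m["t_end"], m["mean_correlation"], m["label"]) for m in obj["modules"]
    ]
    return ModuleSegmentation(mods, obj["threshold"])


# -- meshes: ASCII PLY + JSON manifest --------------------------------------


def write_ply(mesh: TriMeshFrame, path) -> None:
    v, f = mesh.vertices, mesh.faces
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{x:.8g} {y:.8g} {z:.8g}" for x, y, z in v]
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path, time: float = 0.0) -> TriMeshFrame:
    text = Path(path).read_text().splitlines()
    if text[0].strip() != "ply":
        raise ValueError("not a PLY file")
    n_v = n_f = 0
    k = 0
    for k, line in enumerate(text):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_v = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_f = int(parts[2])
        elif parts[:1] == ["end_header"]:
            break
        elif parts[:2] == ["format", "binary_little_endian"] or parts[:2] == [
            "format",
            "binary_big_endian",
        ]:
            raise ValueError("only ASCII PLY is supported")
    body = text[k + 1 :]
    verts = np.array([[float(x) for x in ln.split()[:3]] for ln in body[:n_v]])
    faces = np.array([[int(x) for x in ln.split()[1:4]] for ln in body[n_v : n_v + n_f]])
    return TriMeshFrame(verts, faces, time)


def write_mesh_sequence(seq: MeshSequence, directory, stem: str = "frame") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = []
    for k, m in enumerate(seq):
        name = f"{stem}_{k:04d}.ply"
        write_ply(m, d / name)
        names.append(name)
    manifest = {"times_min": [float(m.time) for m in seq], "files": names}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_mesh_sequence(directory) -> MeshSequence:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    frames = [
        read_ply(d / name, t) for name, t in zip(manifest["files"], manifest["times_min"])
    ]
    return MeshSequence(frames)


def write_deformation_frame(df_: DeformationFrame, path) -> None:
    pd.DataFrame(
        {
            "vertex": np.arange(len(df_.H)),
            "H_per_um": df_.H,
            "vn_um_per_min": df_.v_n,
            "d_per_min": df_.d,
            "valid": df_.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_deformation_frame(path, time: float = 0.0) -> DeformationFrame:
    df = pd.read_csv(path).sort_values("vertex")
    return DeformationFrame(
        df["H_per_um"].to_numpy(),
        df["vn_um_per_min"].to_numpy(),
        df["d_per_min"].to_numpy(),
        df["valid"].to_numpy().astype(bool),
        time,
    )
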