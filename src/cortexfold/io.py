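"""Plain-text export of trajectories, metrics and stability results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_trajectory", "write_metrics", "write_stability",
           "export_snapshot_ply"]


def write_trajectory(traj, outdir, every=1):
    """CSV node tables (id, X, Y, x, y) per snapshot + a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = traj.nodes
    names = []
    for i, st in enumerate(traj.states[::every]):
        d = st.u.reshape(-1, 2)
        df = pd.DataFrame({
            "id": np.arange(len(ref)),
            "X": ref[:, 0], "Y": ref[:, 1],
            "x": ref[:, 0] + d[:, 0], "y": ref[:, 1] + d[:, 1],
        })
        name = f"snapshot_{i:04d}.csv"
        df.to_csv(outdir / name, index=False, float_format="%.10g")
        names.append(name)
    cfg = asdict(traj.config)
    manifest = {
        "thetas": [st.theta for st in traj.states[::every]],
        "files": names,
        "termination": traj.termination,
        "theta_contact": traj.theta_contact,
        "config": cfg,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def write_metrics(metrics, path_csv, path_json=None):
    """Per-snapshot metrics CSV and a JSON summary of the bifurcations."""
    metrics["table"].to_csv(path_csv, index=False, float_format="%.10g")
    if path_json is not None:
        summary = {k: metrics[k] for k in
                   ("theta_first", "theta_second", "theta_contact",
                    "termination")}
        Path(path_json).write_text(json.dumps(summary, indent=1))


def write_stability(result, path_json, path_csv=None):
    """StabilityResult as JSON plus the F1 tabulation as CSV."""
    payload = {
        "beta": result.beta,
        "theta_crit": result.theta_crit,
        "k_crit": result.k_crit,
        "a": result.a,
    }
    Path(path_json).write_text(json.dumps(payload, indent=1))
    if path_csv is not None:
        pd.DataFrame({"Y": result.Y, "F1": result.F1}).to_csv(
            path_csv, index=False, float_format="%.10g")


def export_snapshot_ply(traj, index, path):
    """Deformed mesh of one snapshot as an (extruded-flat) PLY surface."""
    import trimesh

    st = traj.states[index]
    d = st.u.reshape(-1, 2)
    xy = traj.nodes + d
    verts = np.column_stack([xy, np.zeros(len(xy))])
    quads = traj.mesh.conn
    tris = np.vstack([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
    mesh = trimesh.Trimesh(vertices=verts, faces=tris, process=False)
    Path(path).write_bytes(
        trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
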