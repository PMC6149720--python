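"""Readers and writers for the package's plain-text formats.

Peak tables and rocking scans are TSV; structure-factor sets and derived
scalars are JSON; profiles are two-column CSV with a JSON sidecar. Frames
travel either as GRO files (read via MDAnalysis) or as an XYZ dialect whose
comment line carries the periodic box and whose fifth column carries the
residue id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (PEAK_COLUMNS, SCAN_COLUMNS, ContrastSpec, NSLDProfile,
                     ParticleFrame, StructureFactorSet, validate_peak_table)


def write_peak_table(df: pd.DataFrame, path) -> None:
    validate_peak_table(df)
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> pd.DataFrame:
    return validate_peak_table(pd.read_csv(path, sep="\t"))


def read_rocking_scan(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rocking scan missing columns: {missing}")
    return df


def write_structure_factors(sf: StructureFactorSet, path) -> None:
    payload = {
        "D": sf.D,
        "contrasts": [{"d2o_fraction": c.d2o_fraction, "water_nsld": c.water_nsld}
                      for c in sf.contrasts],
        "F_signed": np.asarray(sf.F).tolist(),
        "sigma_F": None if sf.sigma_F is None else np.asarray(sf.sigma_F).tolist(),
        "k": sf.k,
        "f0abs": None if sf.f0abs is None else np.asarray(sf.f0abs).tolist(),
        "diagnostics": sf.diagnostics,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_structure_factors(path) -> StructureFactorSet:
    d = json.loads(Path(path).read_text())
    return StructureFactorSet(
        D=d["D"],
        contrasts=[ContrastSpec(**c) for c in d["contrasts"]],
        F=np.asarray(d["F_signed"], dtype=float),
        sigma_F=None if d.get("sigma_F") is None else np.asarray(d["sigma_F"]),
        k=d.get("k"),
        f0abs=None if d.get("f0abs") is None else np.asarray(d["f0abs"]),
        diagnostics=d.get("diagnostics", {}),
    )


def write_profile(profile: NSLDProfile, csv_path, sidecar_path=None, **extra) -> None:
    pd.DataFrame({"z_angstrom": profile.z, "value": profile.rho}).to_csv(
        csv_path, index=False)
    if sidecar_path is not None:
        meta = {"D": profile.D, "hmax": profile.hmax_used,
                "contrast_d2o_fraction": profile.contrast.d2o_fraction,
                "water_nsld": profile.contrast.water_nsld}
        meta.update(extra)
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_profile(csv_path, sidecar_path) -> NSLDProfile:
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    contrast = ContrastSpec(meta["contrast_d2o_fraction"], meta["water_nsld"])
    return NSLDProfile(z=df["z_angstrom"].to_numpy(), rho=df["value"].to_numpy(),
                       contrast=contrast, D=meta["D"], hmax_used=meta.get("hmax"))


# -- coordinate frames -------------------------------------------------------

def write_frames_xyz(frames: list[ParticleFrame], path) -> None:
    """Write frames in the package XYZ dialect.

    Per frame: atom count; comment line ``box Lx Ly Lz``; atom lines
    ``label x y z resid``.
    """
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{len(frame.positions)}\n")
            fh.write("box {:.6f} {:.6f} {:.6f}\n".format(*frame.box))
            for (x, y, z), lab, rid in zip(frame.positions, frame.labels,
                                           frame.resids):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f} {rid}\n")


def read_frames_xyz(path) -> list[ParticleFrame]:
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1].split()
        if comment[0] != "box":
            raise ValueError("XYZ dialect requires a 'box Lx Ly Lz' comment line")
        box = np.array([float(v) for v in comment[1:4]])
        pos, labels, resids = [], [], []
        for line in lines[i + 2: i + 2 + n]:
            parts = line.split()
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
            resids.append(int(parts[4]) if len(parts) > 4 else len(resids) + 1)
        frames.append(ParticleFrame(np.asarray(pos), np.asarray(labels),
                                    np.asarray(resids), box))
        i += 2 + n
    return frames


def read_frames_gro(path) -> list[ParticleFrame]:
    """Read a GRO coordinate file via MDAnalysis (positions converted to Å)."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    frames = []
    for _ in u.trajectory:
        frames.append(ParticleFrame(
            positions=u.atoms.positions.astype(float),
            labels=np.asarray(u.atoms.names),
            resids=np.asarray(u.atoms.resids, dtype=int),
            box=np.asarray(u.dimensions[:3], dtype=float),
        ))
    return frames


def read_frames(path) -> list[ParticleFrame]:
    path = Path(path)
    if path.suffix.lower() == ".gro":
        return read_frames_gro(path)
    return read_frames_xyz(path)
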