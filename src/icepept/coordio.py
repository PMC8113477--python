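"""Fixed-column coordinate output (PDB, GRO), XYZ trajectories, label maps.

Internal units are Å; GRO files are written in nm as the format requires.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import FrameSet

# species code -> (atom name, residue name)
_SPECIES_NAMES = {
    "OW": ("O", "HOH"),
    "HW": ("H", "HOH"),
    "C_PROBE": ("CP", "PRB"),
    "C_CHAIN": ("C", "PRB"),
    "S_CHAIN": ("S", "PRB"),
    "O_DONOR": ("OD", "PRB"),
    "H_DONOR": ("HD", "PRB"),
}


def _names_for(species: np.ndarray) -> list[tuple[str, str]]:
    return [_SPECIES_NAMES.get(str(s), (str(s)[:2], "UNK")) for s in species]


def write_pdb(frames: FrameSet, path, frame: int | None = None) -> None:
    """Write one frame (or all frames as MODEL records) in fixed-column PDB."""
    which = range(frames.n_frames) if frame is None else [frame]
    names = _names_for(frames.species)
    multi = len(list(which)) > 1
    which = range(frames.n_frames) if frame is None else [frame]
    with open(path, "w") as fh:
        a, b, c = frames.box
        fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for f in which:
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            resid = 0
            last_res = None
            for i, ((aname, rname), xyz) in enumerate(zip(names, frames.coordinates[f])):
                # new residue whenever an oxygen starts a water, or res name changes
                if rname != last_res or (rname == "HOH" and aname == "O"):
                    resid += 1
                    last_res = rname
                serial = (i % 99999) + 1
                fh.write(
                    f"ATOM  {serial:5d} {aname:<4s}{rname:<4s}A{(resid % 9999) + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {aname[0]:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_gro(frames: FrameSet, path, frame: int = 0) -> None:
    """Write one frame in fixed-column GRO (positions in nm)."""
    names = _names_for(frames.species)
    with open(path, "w") as fh:
        fh.write(f"synthetic frame t={frames.times[frame]:.3f} ns\n")
        fh.write(f"{frames.n_atoms:5d}\n")
        resid = 0
        last_res = None
        for i, ((aname, rname), xyz) in enumerate(zip(names, frames.coordinates[frame])):
            if rname != last_res or (rname == "HOH" and aname == "O"):
                resid += 1
                last_res = rname
            x, y, z = xyz / 10.0
            fh.write(f"{(resid % 99999) + 1:5d}{rname:<5s}{aname:>5s}"
                     f"{(i % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
        bx, by, bz = frames.box / 10.0
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def write_xyz(frames: FrameSet, path) -> None:
    """Multi-frame XYZ trajectory.

    The symbol column carries the full species code (OW, HW, C_PROBE, …) so
    a round trip through :func:`read_xyz` preserves atom identities.
    """
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"{frames.n_atoms}\n")
            fh.write(f"t={frames.times[f]:.6f} ns "
                     f"box={frames.box[0]:.4f},{frames.box[1]:.4f},{frames.box[2]:.4f}\n")
            for sp, xyz in zip(frames.species, frames.coordinates[f]):
                fh.write(f"{sp:<8s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


def read_xyz(path, box, times=None, species=None) -> FrameSet:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    frames = []
    syms = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    times_read = []
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        if "t=" in comment:
            times_read.append(float(comment.split("t=")[1].split()[0]))
        block = lines[i + 2:i + 2 + n]
        frames.append([[float(x) for x in ln.split()[1:4]] for ln in block])
        if not syms:
            syms = [ln.split()[0] for ln in block]
        i += 2 + n
    coords = np.array(frames)
    if times is None:
        times = np.array(times_read) if len(times_read) == len(frames) \
            else np.arange(len(frames), dtype=float)
    if species is None:
        # plain-element files (from other tools) map O/H to water codes
        species = np.array(["OW" if s == "O" else "HW" if s == "H" else s
                            for s in syms], dtype=object)
    return FrameSet(coords, species, np.asarray(box, float), times)


def write_label_map_text(label_map: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(label_map, dtype=int), fmt="%d")


def read_label_map_text(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)


def write_label_map_png(label_map: np.ndarray, path) -> None:
    import imageio.v3 as iio
    iio.imwrite(path, np.asarray(label_map, dtype=np.uint16))


def read_label_map_png(path) -> np.ndarray:
    import imageio.v3 as iio
    return np.asarray(iio.imread(path), dtype=int)


def write_metadata_sidecar(frames: FrameSet, path) -> None:
    """JSON sidecar with the embedded ground truth of a generated FrameSet."""
    def _clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v
    meta = {k: _clean(v) for k, v in frames.metadata.items()}
    meta["box"] = frames.box.tolist()
    meta["times_ns"] = [float(frames.times[0]), float(frames.times[-1])]
    meta["n_frames"] = frames.n_frames
    Path(path).write_text(json.dumps(meta, indent=1))
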