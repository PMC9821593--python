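"""Trajectory and topology containers plus text-format I/O.

Units follow the Gromacs convention throughout the package: coordinates in
nm, times in ns, masses in amu, partial charges in elementary charges.
XYZ and PDB files are conventionally in Angstrom and are converted on read
(XYZ dialect defaults to Angstrom; override with ``unit="nm"``).

Atom groups use 0-based indices. A system is partitioned into a dendrimer
atom set and a list of disjoint ligand molecules (index sets); anything
outside those groups (solvent, counter-ions) is simply ignored by the
analyses.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Frame",
    "Topology",
    "Trajectory",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "write_table",
]

#: nm per Angstrom
_NM_PER_ANG = 0.1
#: tolerance for per-frame time vs dt*index consistency (ns)
_TIME_TOL = 1e-6


@dataclass
class Topology:
    """Static description of the system: masses, charges and atom groups.

    Parameters
    ----------
    atom_count : int
        Number of atoms in every frame.
    masses : array of float, shape (atom_count,)
        Atomic masses in amu; must be positive.
    charges : array of float, optional
        Partial charges in e. Required only by the pair-energy analysis.
    dendrimer_atoms : int array
        Indices of the carrier (dendrimer) atoms.
    ligand_molecules : list of int arrays
        One index set per ligand molecule; disjoint from each other and
        from the dendrimer set.
    box : 3-vector, optional
        Orthorhombic box lengths in nm. When present, binding distances
        use the minimum-image convention; trajectories are never re-imaged.
    lj_sigma, lj_epsilon : arrays, optional
        Per-atom Lennard-Jones sigma (nm) and epsilon (kJ/mol).
    """

    atom_count: int
    masses: np.ndarray
    dendrimer_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    ligand_molecules: list = field(default_factory=list)
    charges: Optional[np.ndarray] = None
    box: Optional[np.ndarray] = None
    lj_sigma: Optional[np.ndarray] = None
    lj_epsilon: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim == 0:
            self.masses = np.full(self.atom_count, float(self.masses))
        if self.masses.shape != (self.atom_count,):
            raise ValueError(
                f"masses has shape {self.masses.shape}, expected ({self.atom_count},)"
            )
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be positive")
        self.dendrimer_atoms = np.asarray(self.dendrimer_atoms, dtype=np.intp)
        self.ligand_molecules = [np.asarray(m, dtype=np.intp) for m in self.ligand_molecules]
        for name, arr in [("charges", self.charges), ("lj_sigma", self.lj_sigma),
                          ("lj_epsilon", self.lj_epsilon)]:
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.atom_count,):
                    raise ValueError(f"{name} must have one value per atom")
                setattr(self, name, arr)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive lengths (nm)")
        self._validate_groups()

    def _validate_groups(self) -> None:
        groups = [("dendrimer", self.dendrimer_atoms)] + [
            (f"ligand {i}", m) for i, m in enumerate(self.ligand_molecules)
        ]
        seen = np.zeros(self.atom_count, dtype=bool)
        for name, idx in groups:
            if name.startswith("ligand") and idx.size == 0:
                raise ValueError(f"{name} is empty; ligand molecules must be non-empty")
            if idx.size and (idx.min() < 0 or idx.max() >= self.atom_count):
                bad = idx[(idx < 0) | (idx >= self.atom_count)]
                raise ValueError(
                    f"group '{name}' has out-of-range indices {bad.tolist()} "
                    f"for atom_count={self.atom_count}"
                )
            if np.any(seen[idx]):
                overlap = idx[seen[idx]]
                raise ValueError(
                    f"group '{name}' overlaps earlier groups at indices {overlap.tolist()}"
                )
            seen[idx] = True

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_molecules)


@dataclass
class Frame:
    """One trajectory frame: coordinates in nm and a timestamp in ns."""

    coordinates: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames over a fixed topology."""

    topology: Topology
    frames: list
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.atom_count
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms, topology declares {n}"
                )
        t = self.times
        if np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def window_indices(self, window: Optional[tuple] = None) -> np.ndarray:
        """Indices of frames with t_start <= time <= t_end (1e-9 ns slack)."""
        if window is None:
            return np.arange(self.n_frames)
        t0, t1 = window
        t = self.times
        idx = np.nonzero((t >= t0 - 1e-9) & (t <= t1 + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} contains no frames (span {t[0]}..{t[-1]})")
        return idx


# ---------------------------------------------------------------------------
# topology config


def read_topology(path) -> Topology:
    """Load a topology config (YAML or JSON; JSON is a YAML subset).

    Recognized keys: ``atoms`` (int, required), ``masses`` (scalar or list,
    default 1.0 amu), ``charges``, ``dendrimer`` (index list), ``ligands``
    (list of index lists), ``box`` (3 lengths, nm), ``lj_sigma``,
    ``lj_epsilon``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "atoms" not in cfg:
        raise ValueError(f"{path}: topology config must be a mapping with an 'atoms' key")
    n = int(cfg["atoms"])
    return Topology(
        atom_count=n,
        masses=np.asarray(cfg.get("masses", 1.0), dtype=float),
        charges=None if cfg.get("charges") is None else np.asarray(cfg["charges"], float),
        dendrimer_atoms=np.asarray(cfg.get("dendrimer", []), dtype=np.intp),
        ligand_molecules=[np.asarray(m, dtype=np.intp) for m in cfg.get("ligands", [])],
        box=None if cfg.get("box") is None else np.asarray(cfg["box"], float),
        lj_sigma=None if cfg.get("lj_sigma") is None else np.asarray(cfg["lj_sigma"], float),
        lj_epsilon=None if cfg.get("lj_epsilon") is None else np.asarray(cfg["lj_epsilon"], float),
    )


# ---------------------------------------------------------------------------
# trajectory file formats

_TIME_RE = re.compile(r"\bt\s*=\s*([0-9eE.+-]+)")


def _read_xyz(path, topology: Topology, unit: str, dt: Optional[float]):
    scale = _NM_PER_ANG if unit == "angstrom" else 1.0
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: expected atom count") from exc
        if n_atoms != topology.atom_count:
            raise ValueError(
                f"{path}: frame {n_frame} declares {n_atoms} atoms, "
                f"topology has {topology.atom_count}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        file_time = float(m.group(1)) if m else None
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ValueError(f"{path}: frame {n_frame} truncated at line {ln + 1}")
            parts = lines[ln].split()
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable coordinate at line {ln + 1}") from exc
        frames.append((coords * scale, file_time))
        i += 2 + n_atoms
        n_frame += 1
    return frames


def _read_pdb(path, topology: Topology):
    from biotite.structure.io.pdb import PDBFile

    pdbf = PDBFile.read(str(path))
    stack = pdbf.get_structure(model=None)
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:  # single model comes back as AtomArray
        coords = coords[None]
    if coords.shape[1] != topology.atom_count:
        raise ValueError(
            f"{path}: frame 0 has {coords.shape[1]} atoms, "
            f"topology has {topology.atom_count}"
        )
    return [(c * _NM_PER_ANG, None) for c in coords]


def read_trajectory(path, topology: Topology, format: Optional[str] = None,
                    dt: Optional[float] = None, unit: str = "angstrom") -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB file.

    Frame times come from a per-frame ``t=<ns>`` comment field when present,
    otherwise ``index * dt`` (dt defaults to 1 ns if never declared). When
    both exist and disagree by more than 1e-6 ns, the per-frame field wins
    with a warning.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        raw = _read_xyz(path, topology, unit, dt)
    elif fmt == "pdb":
        raw = _read_pdb(path, topology)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    step = dt if dt is not None else 1.0
    frames = []
    for i, (coords, file_time) in enumerate(raw):
        t_index = i * step
        if file_time is not None:
            if dt is not None and abs(file_time - t_index) > _TIME_TOL:
                warnings.warn(
                    f"frame {i}: file time {file_time} ns disagrees with "
                    f"dt*index {t_index} ns; using file time"
                )
            t = file_time
        else:
            t = t_index
        frames.append(Frame(coordinates=coords, time=t))
    return Trajectory(topology=topology, frames=frames, dt=dt)


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None,
                     unit: str = "angstrom") -> None:
    """Write a trajectory as multi-frame XYZ (with ``t=`` comments) or
    multi-model PDB. Coordinates are emitted in Angstrom by default."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        scale = 1.0 / _NM_PER_ANG if unit == "angstrom" else 1.0
        with open(path, "w") as fh:
            for fr in traj.frames:
                fh.write(f"{fr.n_atoms}\n")
                fh.write(f"t={fr.time:.6f}\n")
                for x, y, z in fr.coordinates * scale:
                    fh.write(f"X {x:.5f} {y:.5f} {z:.5f}\n")
    elif fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = traj.topology.atom_count
        stack = struc.AtomArrayStack(traj.n_frames, n)
        stack.coord = np.stack([fr.coordinates for fr in traj.frames]) / _NM_PER_ANG
        stack.atom_name = np.full(n, "C")
        stack.element = np.full(n, "C")
        stack.res_name = np.full(n, "UNK")
        stack.res_id = np.ones(n, dtype=int)
        stack.chain_id = np.full(n, "A")
        stack.hetero = np.zeros(n, dtype=bool)
        pdbf = PDBFile()
        pdbf.set_structure(stack)
        pdbf.write(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# result tables


def _round_sig(x, sig=6):
    return float(f"{float(x):.{sig}g}")


def write_table(rows: Sequence[dict], path, format: str = "tsv",
                columns: Optional[Sequence[str]] = None) -> None:
    """Write homogeneous records as TSV or JSON with 6-significant-digit
    floats, so identical inputs give byte-identical files."""
    if rows:
        keys = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != keys:
                raise ValueError("records are not homogeneous")
    else:
        keys = list(columns or [])
    df = pd.DataFrame(list(rows), columns=keys)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        recs = [
            {k: (_round_sig(v) if isinstance(v, float) else v) for k, v in r.items()}
            for r in rows
        ]
        with open(path, "w") as fh:
            json.dump(recs, fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_table(path, format: Optional[str] = None) -> pd.DataFrame:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        return pd.read_json(path)
    raise ValueError(f"unsupported table format {fmt!r}")
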