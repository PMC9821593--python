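"""Ligand-binding classification and statistics on trajectories.

A ligand molecule is *bound* at a frame when the minimum distance between
any of its atoms and any dendrimer atom is strictly below the cutoff
(default 3.5 Angstrom). From the per-ligand boolean series this module
derives bound-count time series, residence-time summaries (persistent
vs transient binders around a threshold tau, default 10 ns), dendrimer-COM
to ligand-COM radial distribution functions, and cutoff-truncated
Lennard-Jones + Coulomb pair interaction energies.

Distance conventions: binding cutoffs and RDF bins are expressed in
Angstrom (the field's habit for contact criteria); coordinates are stored
in nm and converted internally. If the topology declares a box, distances
use the minimum image on the wrapped coordinates; nothing is re-imaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "BindingSeries",
    "ResidenceSummary",
    "RDFCurve",
    "PairEnergy",
    "classify_binding",
    "bound_count_series",
    "residence_summary",
    "com_rdf",
    "pair_interaction_energy",
    "mean_pair_energy",
    "F_COULOMB",
]

#: Coulomb conversion factor e**2/(4 pi eps0) in kJ mol^-1 nm e^-2
#: (Gromacs convention, f = 138.935458)
F_COULOMB = 138.935458

_ANG_PER_NM = 10.0
#: slack on run-duration comparison against tau (ns); a run spanning
#: exactly tau is transient ("more than tau" is strict)
_TAU_TOL = 1e-9


@dataclass
class BindingSeries:
    """Per-ligand bound/unbound boolean series at a distance cutoff."""

    cutoff: float                 # Angstrom
    times: np.ndarray             # ns, shape (n_frames,)
    bound: np.ndarray             # bool, shape (n_ligands, n_frames)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.bound.ndim != 2 or self.bound.shape[1] != self.times.size:
            raise ValueError("bound must have shape (n_ligands, n_frames)")

    @property
    def n_ligands(self) -> int:
        return self.bound.shape[0]

    def window_mask(self, window: Optional[tuple]) -> np.ndarray:
        if window is None:
            return np.ones(self.times.size, dtype=bool)
        t0, t1 = window
        mask = (self.times >= t0 - _TAU_TOL) & (self.times <= t1 + _TAU_TOL)
        if not mask.any():
            raise ValueError(f"window {window} contains no frames")
        return mask


def _min_ligand_distances(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Min distance (nm) from each ligand molecule to the dendrimer set."""
    dend = coords[topology.dendrimer_atoms]
    lig_atoms = np.concatenate(topology.ligand_molecules)
    lig = coords[lig_atoms]
    if topology.box is not None:
        box = topology.box
        tree = cKDTree(np.mod(dend, box), boxsize=box)
        d, _ = tree.query(np.mod(lig, box))
    else:
        tree = cKDTree(dend)
        d, _ = tree.query(lig)
    starts = np.cumsum([0] + [m.size for m in topology.ligand_molecules[:-1]])
    return np.minimum.reduceat(d, starts)


def classify_binding(traj: Trajectory, cutoff: float = 3.5) -> BindingSeries:
    """Classify each ligand at each frame; ``cutoff`` in Angstrom, strict <."""
    top = traj.topology
    if top.n_ligands == 0:
        raise ValueError("topology declares no ligand molecules")
    if top.dendrimer_atoms.size == 0:
        raise ValueError("topology declares no dendrimer atoms")
    cutoff_nm = cutoff / _ANG_PER_NM
    bound = np.empty((top.n_ligands, traj.n_frames), dtype=bool)
    for j, fr in enumerate(traj.frames):
        bound[:, j] = _min_ligand_distances(fr.coordinates, top) < cutoff_nm
    return BindingSeries(cutoff=cutoff, times=traj.times, bound=bound)


def bound_count_series(bs: BindingSeries, window: Optional[tuple] = None):
    """Instantaneous number of bound ligands per frame, plus its mean over
    ``window`` (default: whole series). Returns ``(counts, window_mean)``."""
    counts = bs.bound.sum(axis=0)
    mask = bs.window_mask(window)
    return counts, float(counts[mask].mean())


def _runs(flags: np.ndarray):
    """Contiguous True runs as (start, end) inclusive frame indices."""
    padded = np.diff(np.concatenate(([0], flags.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1
    return list(zip(starts, ends))


@dataclass
class ResidenceSummary:
    """Persistent/transient binder counts within an analysis window.

    Runs are segmented on the full series; a ligand is persistent
    (``n_long``) if any bound run intersecting the window lasts more than
    ``tau`` ns, transient (``n_short``) if it was bound in the window but
    only in runs of at most tau. Ligands never bound in the window are
    excluded, so n_long + n_short equals the number of distinct binders.
    """

    window: tuple
    tau: float
    n_long: int
    n_short: int
    mean_bound: float
    long_ligands: list = field(default_factory=list)
    short_ligands: list = field(default_factory=list)

    def as_record(self) -> dict:
        return {
            "t_start_ns": self.window[0], "t_end_ns": self.window[1],
            "tau_ns": self.tau, "N_long": self.n_long, "N_short": self.n_short,
            "mean_bound": self.mean_bound,
        }


def residence_summary(bs: BindingSeries, window: Optional[tuple] = None,
                      tau: float = 10.0) -> ResidenceSummary:
    if tau <= 0:
        raise ValueError("tau must be positive")
    mask = bs.window_mask(window)
    win_idx = np.nonzero(mask)[0]
    lo, hi = win_idx[0], win_idx[-1]
    t = bs.times
    long_l, short_l = [], []
    for lig in range(bs.n_ligands):
        flags = bs.bound[lig]
        if not flags[mask].any():
            continue
        is_long = False
        for start, end in _runs(flags):
            if end < lo or start > hi:
                continue
            if t[end] - t[start] > tau + _TAU_TOL:
                is_long = True
                break
        (long_l if is_long else short_l).append(lig)
    _, mean_bound = bound_count_series(bs, window)
    win = (float(t[lo]), float(t[hi])) if window is None else (float(window[0]), float(window[1]))
    return ResidenceSummary(window=win, tau=tau, n_long=len(long_l),
                            n_short=len(short_l), mean_bound=mean_bound,
                            long_ligands=long_l, short_ligands=short_l)


# ---------------------------------------------------------------------------
# radial distribution function


@dataclass
class RDFCurve:
    bin_centers: np.ndarray       # Angstrom
    g: np.ndarray
    bin_width: float              # Angstrom
    n_frames: int
    counts: np.ndarray = None     # raw pair counts per bin, all frames

    def as_records(self):
        return [
            {"r_A": float(r), "g": float(gv)}
            for r, gv in zip(self.bin_centers, self.g)
        ]


def com_rdf(traj: Trajectory, window: Optional[tuple] = None,
            bin_width: float = 1.0, r_max: float = 40.0) -> RDFCurve:
    """g(r) of ligand-molecule COMs about the dendrimer COM (r in Angstrom).

    Normalized by spherical-shell volume and by the mean ligand-COM number
    density inside the analysis sphere of radius ``r_max``, so a uniform
    distribution in that sphere gives g ~ 1 and the large-r tail sits at
    the bulk level.
    """
    if not (r_max > bin_width > 0):
        raise ValueError("need r_max > bin_width > 0")
    top = traj.topology
    if top.n_ligands == 0:
        raise ValueError("topology declares no ligand molecules")
    idx = traj.window_indices(window)
    m = top.masses
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1)
    n_inside = 0
    dend = top.dendrimer_atoms
    md = m[dend]
    for i in idx:
        x = traj.frames[i].coordinates
        com_d = (md[:, None] * x[dend]).sum(axis=0) / md.sum()
        lig_coms = np.array([
            (m[mol, None] * x[mol]).sum(axis=0) / m[mol].sum()
            for mol in top.ligand_molecules
        ])
        r = np.linalg.norm(lig_coms - com_d, axis=1) * _ANG_PER_NM
        counts += np.histogram(r, bins=edges)[0]
        n_inside += int((r < r_max).sum())
    n_frames = idx.size
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = n_inside / (n_frames * 4.0 / 3.0 * np.pi * r_max ** 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / (n_frames * shell_vol * rho) if rho > 0 else np.zeros_like(counts)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(bin_centers=centers, g=g, bin_width=bin_width,
                    n_frames=n_frames, counts=counts)


# ---------------------------------------------------------------------------
# pair interaction energies


@dataclass
class PairEnergy:
    """Cutoff-truncated dendrimer-ligand interaction energy (kJ/mol)."""

    lj: float
    coul: float
    total: float
    per_ligand_mean: float
    n_ligands: int


def pair_interaction_energy(frame: Frame, topology: Topology,
                            lj_sigma=None, lj_epsilon=None, charges=None,
                            cutoff: float = 1.2,
                            ligand_subset: Optional[Sequence[int]] = None) -> PairEnergy:
    """LJ + Coulomb energy between the dendrimer and ligand molecules.

    ``lj_sigma`` (nm), ``lj_epsilon`` (kJ/mol) and ``charges`` (e) default
    to the per-atom arrays on the topology. Pairs beyond ``cutoff`` (nm)
    are dropped (plain truncation; no reciprocal-space term). Mixing is
    Lorentz-Berthelot: sigma arithmetic, epsilon geometric.
    """
    sigma = lj_sigma if lj_sigma is not None else topology.lj_sigma
    eps = lj_epsilon if lj_epsilon is not None else topology.lj_epsilon
    q = charges if charges is not None else topology.charges
    if sigma is None or eps is None:
        raise ValueError("LJ parameters missing: provide lj_sigma/lj_epsilon "
                         "or declare them in the topology config")
    if q is None:
        raise ValueError("charges missing: declare 'charges' in the topology "
                         "config or pass them explicitly")
    sigma = np.asarray(sigma, float)
    eps = np.asarray(eps, float)
    q = np.asarray(q, float)

    mols = topology.ligand_molecules
    if ligand_subset is not None:
        mols = [mols[i] for i in ligand_subset]
    if not mols:
        raise ValueError("no ligand molecules selected")
    dend = topology.dendrimer_atoms
    lig = np.concatenate(mols)
    r = cdist(frame.coordinates[dend], frame.coordinates[lig])
    within = r < cutoff
    np.clip(r, 1e-12, None, out=r)

    sig_ij = 0.5 * (sigma[dend][:, None] + sigma[lig][None, :])
    eps_ij = np.sqrt(eps[dend][:, None] * eps[lig][None, :])
    sr6 = (sig_ij / r) ** 6
    e_lj = float((4.0 * eps_ij * (sr6 * sr6 - sr6))[within].sum())
    e_coul = float((F_COULOMB * q[dend][:, None] * q[lig][None, :] / r)[within].sum())
    total = e_lj + e_coul
    return PairEnergy(lj=e_lj, coul=e_coul, total=total,
                      per_ligand_mean=total / len(mols), n_ligands=len(mols))


def mean_pair_energy(traj: Trajectory, window: Optional[tuple] = None,
                     lj_sigma=None, lj_epsilon=None, charges=None,
                     cutoff: float = 1.2, averaging: str = "bound",
                     binding: Optional[BindingSeries] = None,
                     binding_cutoff: float = 3.5) -> PairEnergy:
    """Time-averaged per-ligand pair energy over a window.

    ``averaging="bound"`` (default) divides each frame's energy by the
    number of ligands bound at that frame (frames with none are skipped);
    ``"all"`` divides by the total ligand count. The per-frame energy is
    always summed over all ligand molecules within the cutoff.
    """
    idx = traj.window_indices(window)
    if averaging == "bound" and binding is None:
        binding = classify_binding(traj, cutoff=binding_cutoff)
    lj_l, coul_l, per_l = [], [], []
    for i in idx:
        pe = pair_interaction_energy(traj.frames[i], traj.topology,
                                     lj_sigma, lj_epsilon, charges, cutoff)
        lj_l.append(pe.lj)
        coul_l.append(pe.coul)
        if averaging == "bound":
            n = int(binding.bound[:, i].sum())
            if n > 0:
                per_l.append(pe.total / n)
        else:
            per_l.append(pe.per_ligand_mean)
    lj = float(np.mean(lj_l))
    coul = float(np.mean(coul_l))
    return PairEnergy(lj=lj, coul=coul, total=lj + coul,
                      per_ligand_mean=float(np.mean(per_l)) if per_l else 0.0,
                      n_ligands=traj.topology.n_ligands)
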