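"""Synthetic inputs with known ground truth for every analysis stage.

No dynamics are simulated. The generators emit:

* bead clouds sampled uniformly inside an ellipsoid, with the analytic
  Rg**2 = (a**2 + b**2 + c**2)/5 and gyration eigenvalues (a**2/5, ...)
  attached -- oracles for the shape metrics;
* scripted binding trajectories: single-bead ligands that sit within a
  prescribed bound radius of a random dendrimer surface atom during
  scripted (t_on, t_off) intervals and far outside otherwise, returned
  together with the exact bound/unbound truth series -- the oracle for
  the binding classifier and residence statistics;
* sphere-form-factor SAXS curves I = I0 [3 (sin qR - qR cos qR)/(qR)**3]**2
  with optional multiplicative Gaussian noise -- oracle for Guinier fits
  (sphere Rg = sqrt(3/5) R);
* Stejskal-Tanner DOSY decays -- oracle for the diffusion fit.

Every generator is a pure function of (parameters, seed).

The S1/S2/S3 binding scenarios mirror a 100-ligand system at increasing
carrier protonation: mean window occupancies 5/16/25 with
persistent/transient binder splits (0, 8), (6, 12), (12, 13) in the final
10 ns of a 100 ns trajectory. Occupancy is realized by slot coverage:
persistent ligands stay bound from 40 ns to the end (runs > 10 ns), and
transient ligands tile the final window in runs of at most 10 ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .binding import BindingSeries
from .solution import GAMMA_1H, DOSYDecay, SAXSCurve
from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "EllipsoidSpec",
    "BindingScript",
    "make_ellipsoid_cloud",
    "make_binding_trajectory",
    "scenario_script",
    "make_scenario_trajectory",
    "make_sphere_saxs",
    "make_dosy_decay",
    "dosy_gradient_ramp",
    "SCENARIOS",
]

_ANG_PER_NM = 10.0
_TOL = 1e-9


# ---------------------------------------------------------------------------
# bead conformers


@dataclass
class EllipsoidSpec:
    """Uniform bead cloud inside an ellipsoid with semi-axes (a, b, c) nm."""

    semi_axes: Tuple[float, float, float]
    n_beads: int = 1000
    mass: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.n_beads < 4:
            raise ValueError("need at least 4 beads")


def make_ellipsoid_cloud(spec: EllipsoidSpec):
    """Sample the cloud; returns (Frame, Topology, ground_truth).

    ground_truth carries the analytic uniform-ellipsoid values:
    ``rg`` = sqrt((a^2+b^2+c^2)/5) nm and ``gyration_eigenvalues`` =
    sorted (a^2/5, b^2/5, c^2/5) nm^2.
    """
    rng = np.random.default_rng(spec.seed)
    v = rng.normal(size=(spec.n_beads, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.random(spec.n_beads) ** (1.0 / 3.0)
    coords = v * r[:, None] * np.asarray(spec.semi_axes)
    frame = Frame(coordinates=coords, time=0.0)
    top = Topology(
        atom_count=spec.n_beads,
        masses=np.full(spec.n_beads, spec.mass),
        dendrimer_atoms=np.arange(spec.n_beads),
    )
    a2 = np.asarray(spec.semi_axes) ** 2
    truth = {
        "rg": float(np.sqrt(a2.sum() / 5.0)),
        "gyration_eigenvalues": tuple(np.sort(a2 / 5.0)),
    }
    return frame, top, truth


# ---------------------------------------------------------------------------
# scripted binding trajectories


@dataclass
class BindingScript:
    """Per-ligand bound intervals (t_on, t_off) ns, half-open [t_on, t_off).

    ``bound_radius`` / ``unbound_radius`` (Angstrom) are the placement
    distances of a ligand's bead from the dendrimer atom set while bound /
    unbound; a binding cutoff between them reproduces the script exactly.
    """

    n_ligands: int
    intervals: list                 # list (per ligand) of [(t_on, t_off), ...]
    bound_radius: float = 3.0
    unbound_radius: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intervals) != self.n_ligands:
            raise ValueError("need one interval list per ligand")
        if not 0 < self.bound_radius < self.unbound_radius:
            raise ValueError("need 0 < bound_radius < unbound_radius")
        for lig, ivals in enumerate(self.intervals):
            prev_off = -np.inf
            for t_on, t_off in ivals:
                if t_off <= t_on:
                    raise ValueError(f"ligand {lig}: empty interval ({t_on}, {t_off})")
                if t_on < prev_off:
                    raise ValueError(f"ligand {lig}: overlapping/unsorted intervals")
                prev_off = t_off

    def truth_series(self, times: np.ndarray, cutoff: float = 3.5) -> BindingSeries:
        bound = np.zeros((self.n_ligands, times.size), dtype=bool)
        for lig, ivals in enumerate(self.intervals):
            for t_on, t_off in ivals:
                bound[lig] |= (times >= t_on - _TOL) & (times < t_off - _TOL)
        return BindingSeries(cutoff=cutoff, times=times, bound=bound)


def make_binding_trajectory(script: BindingScript, dt: float, t_end: float,
                            dendrimer: Frame, dendrimer_masses=None,
                            cutoff: float = 3.5, ligand_mass: float = 130.0):
    """Materialize a script as a Trajectory of a static dendrimer plus
    single-bead ligands; returns (Trajectory, ground-truth BindingSeries).

    During each interval the ligand bead sits ``bound_radius`` Angstrom
    from a script-chosen dendrimer atom (so its minimum distance is below
    any cutoff > bound_radius); otherwise it sits radially outside the
    whole cloud with minimum distance at least ``unbound_radius``.
    """
    if not script.bound_radius < cutoff < script.unbound_radius:
        raise ValueError(
            f"cutoff {cutoff} A must lie strictly between bound_radius "
            f"{script.bound_radius} and unbound_radius {script.unbound_radius}"
        )
    for ivals in script.intervals:
        for t_on, t_off in ivals:
            if t_on < -_TOL or t_on > t_end + _TOL:
                raise ValueError(f"interval start {t_on} outside [0, {t_end}]")

    rng = np.random.default_rng(script.seed)
    dcoords = dendrimer.coordinates
    n_d = dcoords.shape[0]
    com = dcoords.mean(axis=0)
    extent = float(np.linalg.norm(dcoords - com, axis=1).max())

    def rand_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    bound_nm = script.bound_radius / _ANG_PER_NM
    unbound_nm = script.unbound_radius / _ANG_PER_NM
    unbound_pos = np.empty((script.n_ligands, 3))
    bound_pos = []  # per ligand: list of positions, one per interval
    for lig in range(script.n_ligands):
        unbound_pos[lig] = com + rand_dir() * (extent + unbound_nm)
        positions = []
        for _ in script.intervals[lig]:
            anchor = dcoords[rng.integers(n_d)]
            positions.append(anchor + rand_dir() * bound_nm)
        bound_pos.append(positions)

    n_frames = int(round(t_end / dt)) + 1
    times = np.arange(n_frames) * dt
    truth = script.truth_series(times, cutoff=cutoff)

    frames = []
    for j, t in enumerate(times):
        lig_xyz = unbound_pos.copy()
        for lig, ivals in enumerate(script.intervals):
            for k, (t_on, t_off) in enumerate(ivals):
                if t_on - _TOL <= t < t_off - _TOL:
                    lig_xyz[lig] = bound_pos[lig][k]
                    break
        frames.append(Frame(coordinates=np.vstack([dcoords, lig_xyz]), time=float(t)))

    if dendrimer_masses is None:
        dendrimer_masses = np.full(n_d, 14.0)
    top = Topology(
        atom_count=n_d + script.n_ligands,
        masses=np.concatenate([dendrimer_masses,
                               np.full(script.n_ligands, ligand_mass)]),
        dendrimer_atoms=np.arange(n_d),
        ligand_molecules=[np.array([n_d + i]) for i in range(script.n_ligands)],
    )
    return Trajectory(topology=top, frames=frames, dt=dt), truth


# ---------------------------------------------------------------------------
# named scenarios

#: (n_persistent, n_split_slots, n_full_slots) per scenario; each split
#: slot holds two ligands tiling the window, each full slot one ligand
#: bound for exactly the window (a run of 10 ns, i.e. not more than tau).
_SCENARIO_PLAN = {"S1": (0, 3, 2), "S2": (6, 2, 8), "S3": (12, 0, 13)}

SCENARIOS = {
    "S1": {"mean_bound": 5.0, "n_long": 0, "n_short": 8},
    "S2": {"mean_bound": 16.0, "n_long": 6, "n_short": 12},
    "S3": {"mean_bound": 25.0, "n_long": 12, "n_short": 13},
}


def scenario_script(name: str, n_ligands: int = 100, t_end: float = 100.0,
                    window: Tuple[float, float] = (90.0, 100.0),
                    dt: float = 0.1, seed: int = 0) -> BindingScript:
    """Binding script for scenario S1/S2/S3 (see module docstring)."""
    if name not in _SCENARIO_PLAN:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIO_PLAN)}")
    n_pers, n_split, n_full = _SCENARIO_PLAN[name]
    w0, w1 = window
    mid = 0.5 * (w0 + w1)
    past_end = t_end + dt  # half-open interval covering the final frame
    intervals = []
    for _ in range(n_pers):
        intervals.append([(w0 - 50.0, past_end)])
    for _ in range(n_split):
        intervals.append([(w0, mid)])
        intervals.append([(mid, past_end)])
    for _ in range(n_full):
        intervals.append([(w0, past_end)])
    n_binders = len(intervals)
    if n_binders > n_ligands:
        raise ValueError(f"scenario needs at least {n_binders} ligands")
    intervals.extend([[] for _ in range(n_ligands - n_binders)])
    return BindingScript(n_ligands=n_ligands, intervals=intervals, seed=seed)


def make_scenario_trajectory(name: str, seed: int = 0, n_ligands: int = 100,
                             t_end: float = 100.0, dt: float = 0.1,
                             window: Tuple[float, float] = (90.0, 100.0),
                             dendrimer_beads: int = 150,
                             dendrimer_radius: float = 2.0):
    """Full scripted system for a scenario: a spherical dendrimer bead
    cloud plus scripted ligands. Returns (Trajectory, truth BindingSeries,
    expected summary dict with mean_bound / n_long / n_short)."""
    script = scenario_script(name, n_ligands=n_ligands, t_end=t_end,
                             window=window, dt=dt, seed=seed)
    dend, _, _ = make_ellipsoid_cloud(EllipsoidSpec(
        semi_axes=(dendrimer_radius,) * 3, n_beads=dendrimer_beads, seed=seed + 1))
    traj, truth = make_binding_trajectory(script, dt=dt, t_end=t_end, dendrimer=dend)
    return traj, truth, dict(SCENARIOS[name], window=window)


# ---------------------------------------------------------------------------
# scattering and diffusion curves


def _sphere_form_factor(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x)/x**3, with the x -> 0 limit handled."""
    x = np.asarray(x, dtype=float)
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    f = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return np.where(small, 1.0 - x ** 2 / 10.0, f)


def make_sphere_saxs(radius: float, i0: float = 1.0, q_grid=None,
                     noise_sd: float = 0.0, seed: int = 0) -> SAXSCurve:
    """Homogeneous-sphere SAXS curve; ``radius`` nm, ``q_grid`` nm^-1
    (default 100 points on 0.05..3), multiplicative Gaussian noise of
    relative sd ``noise_sd``. Sphere ground truth: Rg = sqrt(3/5) R."""
    if q_grid is None:
        q_grid = np.linspace(0.05, 3.0, 100)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be positive and increasing")
    intensity = i0 * _sphere_form_factor(q * radius) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_sd * rng.standard_normal(q.size))
    return SAXSCurve(q=q, intensity=intensity)


def dosy_gradient_ramp(g_max: float = 0.5, n_steps: int = 25,
                       start: float = 0.02, stop: float = 0.95) -> np.ndarray:
    """Linear gradient ramp: ``n_steps`` points from ``start`` to ``stop``
    of the maximum strength ``g_max`` (T/m)."""
    return np.linspace(start, stop, n_steps) * g_max


def make_dosy_decay(d: float, delta: float = 2.8e-3, big_delta: float = 0.35,
                    gradients=None, gamma: float = GAMMA_1H, i0: float = 1.0,
                    noise_sd: float = 0.0, seed: int = 0) -> DOSYDecay:
    """Stejskal-Tanner decay for diffusion coefficient ``d`` (m^2/s).

    Default pulse timings (delta = 2.8 ms total bipolar pulse, Delta =
    350 ms) with the 25-step 2-95% ramp attenuate a D ~ 8e-11 m^2/s
    signal to a few percent residual, the regime a BPPLED experiment on
    a dendrimer is tuned to. Noise is multiplicative Gaussian.
    """
    if gradients is None:
        gradients = dosy_gradient_ramp()
    g = np.asarray(gradients, dtype=float)
    b = (gamma * delta * g) ** 2 * (big_delta - delta / 3.0)
    intensity = i0 * np.exp(-d * b)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_sd * rng.standard_normal(g.size))
        intensity = np.clip(intensity, 1e-12, None)
    return DOSYDecay(gradient=g, intensity=intensity, delta=delta,
                     big_delta=big_delta, gamma=gamma)
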