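"""Center-of-mass radial distribution function of ligands.

Places two scripted ligand populations around a central dendrimer: an
inner shell at 5 A (encapsulated in the core) and one at 13 A (inside
the branch region), plus a diffuse outer cloud. The COM-COM g(r) then
shows the two sharp localization peaks over a flat bulk background.
"""

import numpy as np

from dendrikit import Frame, Topology, Trajectory, com_rdf

rng = np.random.default_rng(11)
n_shell1, n_shell2, n_bulk, n_frames = 8, 12, 60, 40
n_lig = n_shell1 + n_shell2 + n_bulk

topology = Topology(
    atom_count=1 + n_lig,
    masses=np.ones(1 + n_lig),
    dendrimer_atoms=np.array([0]),
    ligand_molecules=[np.array([1 + i]) for i in range(n_lig)],
)

frames = []
for k in range(n_frames):
    v = rng.normal(size=(n_lig, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii_nm = np.concatenate([
        0.5 + rng.uniform(-0.03, 0.03, n_shell1),    # 5 A shell
        1.3 + rng.uniform(-0.03, 0.03, n_shell2),    # 13 A shell
        4.0 * rng.random(n_bulk) ** (1 / 3),         # uniform bulk
    ])
    frames.append(Frame(np.vstack([np.zeros(3), v * radii_nm[:, None]]),
                        time=0.1 * k))
traj = Trajectory(topology=topology, frames=frames, dt=0.1)

rdf = com_rdf(traj, bin_width=1.0, r_max=40.0)
for r, g in zip(rdf.bin_centers, rdf.g):
    bar = "#" * int(min(g, 40))
    if g > 0.05:
        print(f"r = {r:4.1f} A   g = {g:7.2f}  {bar}")
print()
print("The spikes at ~5 A and ~13 A are the scripted localization shells;")
print("shell-volume normalization puts the diffuse outer population near")
print("g = 1, the bulk level.")
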