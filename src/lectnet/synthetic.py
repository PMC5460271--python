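"""Synthetic generators with planted ground truth.

Everything the analysis consumes can be generated here with known answers:

* ``make_toy_dimer`` — a two-chain structure whose designed contact patch is
  buried on complexation, for testing SASA-based residue classification;
* ``simulate_trajectory`` — Gaussian-fluctuation trajectories whose
  residue–residue motion correlation equals a planted matrix in expectation;
* ``make_bottleneck_system`` — a trajectory whose residue network funnels
  all inter-module communication through one planted bridge residue;
* ``sample_potts_msa`` — alignments Gibbs-sampled from a pairwise (Potts)
  sequence model with planted coupled column pairs.

The generators match the statistical assumptions of the analysis, not
molecular physics: no force field, solvent or thermostat is emulated.
Every generator returns a machine-readable manifest of its ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import minimize

from .dca import ALPHABET, Alignment
from .network import Trajectory
from .structure import Atom, Structure

__all__ = [
    "TrajectorySpec",
    "PottsSpec",
    "make_toy_dimer",
    "simulate_trajectory",
    "make_bottleneck_system",
    "sample_potts_msa",
    "contact_topology",
    "structure_to_pdb",
    "trajectory_to_pdb",
    "alignment_to_fasta",
]


# ---------------------------------------------------------------------------
# PDB / FASTA writers (plain-text round-trip for the pipeline readers)


def _pdb_atom_line(serial: int, a: Atom, xyz: np.ndarray) -> str:
    record = "HETATM" if a.is_hetero else "ATOM"
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{a.resname:>4s} {a.chain:1s}"
        f"{a.resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def structure_to_pdb(s: Structure, model: int = 0) -> str:
    lines = []
    for i, a in enumerate(s.atoms):
        lines.append(_pdb_atom_line(i + 1, a, s.coords[model, i]))
    lines.append("END")
    return "\n".join(lines) + "\n"


def trajectory_to_pdb(t: Trajectory) -> str:
    lines = []
    for m in range(t.n_frames):
        lines.append(f"MODEL     {m + 1:>4d}")
        for i, a in enumerate(t.topology.atoms):
            lines.append(_pdb_atom_line(i + 1, a, t.frames[m, i]))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def alignment_to_fasta(a: Alignment) -> str:
    out = []
    for name, seq in zip(a.ids, a.sequences()):
        out.append(f">{name}\n{seq}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# toy dimer with a designed buried patch


def _backbone_residue(chain: str, resnum: int, origin: np.ndarray) -> tuple[list[Atom], list[np.ndarray]]:
    """A compact 5-heavy-atom pseudo-residue (ALA-like) at ``origin``."""
    offsets = {
        "N": (-1.2, 0.9, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.2, 0.9, 0.0),
        "O": (1.3, 2.1, 0.0),
        "CB": (0.0, -1.0, 1.1),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    atoms, coords = [], []
    for name, off in offsets.items():
        atoms.append(Atom(chain, resnum, "ALA", name, elements[name]))
        coords.append(origin + np.asarray(off))
    return atoms, coords


def make_toy_dimer(
    n_residues_per_chain: int = 10,
    seed: int = 0,
) -> tuple[Structure, Structure, Structure, dict]:
    """Synthetic dimer with a designed, unambiguously buried contact patch.

    Chain A is an extended pseudo-peptide along the x axis; chain B is a
    tight atomic cage wrapped around the middle third of chain A, so those
    patch residues are solvent exposed in the isolated monomer and buried in
    the complex, with wide margins on both sides of the standard 20 %
    relative-SASA threshold.  Returns ``(monomer_a, monomer_b, dimer,
    manifest)`` where the manifest records the planted interface set of each
    chain, the designed cross-chain contact pairs and the seed.
    """
    n = n_residues_per_chain
    if n < 5:
        raise ValueError("need at least 5 residues per chain")
    rng = np.random.default_rng(seed)

    spacing = 3.8
    patch = list(range(n // 3, n // 3 + max(2, n // 4) + 1))

    atoms_a: list[Atom] = []
    coords_a: list[np.ndarray] = []
    for i in range(n):
        origin = np.array([spacing * i, 0.0, 0.0]) + rng.normal(0, 0.03, 3)
        a, c = _backbone_residue("A", i + 1, origin)
        atoms_a += a
        coords_a += c

    # chain B: n "rail" residues of 5 atoms each on a cylinder of radius 4.0
    # around the patch x-range (cage walls midway between patch and neighbour
    # residues), closed by annular end caps; the grid spacing stays < 3 A so
    # a 1.4 A probe cannot enter and the patch is unambiguously buried.
    # the pseudo-residue is x-asymmetric (C/O atoms extend toward +x), so the
    # left wall sits closer to the patch to keep the left neighbour exposed
    x0 = spacing * patch[0] - 0.7
    x1 = spacing * patch[-1] + 1.6
    stations = np.linspace(x0, x1, max(5, int((x1 - x0) / 2.4) + 1))
    radius = 4.0
    atoms_b: list[Atom] = []
    coords_b: list[np.ndarray] = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n + rng.normal(0, 0.005)
        y = radius * math.cos(theta)
        z = radius * math.sin(theta)
        for s, xs in enumerate(stations):
            name = "CA" if s == 0 else f"C{s}"
            atoms_b.append(Atom("B", k + 1, "ALA", name, "C"))
            coords_b.append(np.array([xs, y, z]) + rng.normal(0, 0.03, 3))
    # end caps: one ring of 8 atoms at radius 2.6 in each end plane, parked
    # on the first 8 rail residues under distinct atom names
    for cap, xs in enumerate((x0, x1)):
        for k in range(8):
            theta = 2.0 * math.pi * (k + 0.5) / 8
            pos = np.array([xs, 2.6 * math.cos(theta), 2.6 * math.sin(theta)])
            atoms_b.append(Atom("B", k + 1, "ALA", f"D{cap + 1}", "C"))
            coords_b.append(pos + rng.normal(0, 0.03, 3))

    monomer_a = Structure(atoms_a, np.asarray(coords_a)[None])
    monomer_b = Structure(atoms_b, np.asarray(coords_b)[None])
    dimer = Structure(
        atoms_a + atoms_b,
        np.concatenate([coords_a, coords_b])[None],
    )

    xyz_a = np.asarray(coords_a)
    xyz_b = np.asarray(coords_b)
    contact_pairs = set()
    for i, atom_a in enumerate(atoms_a):
        d = np.linalg.norm(xyz_b - xyz_a[i], axis=1)
        for j in np.flatnonzero(d < 4.0):
            contact_pairs.add((atoms_a[i].resnum, atoms_b[j].resnum))
    manifest = {
        "seed": seed,
        "n_residues_per_chain": n,
        "interface": {"A": [i + 1 for i in patch], "B": []},
        "contact_pairs_4A": sorted(contact_pairs),
    }
    return monomer_a, monomer_b, dimer, manifest


# ---------------------------------------------------------------------------
# trajectories with planted correlation


@dataclass
class TrajectorySpec:
    """Recipe for a Gaussian-fluctuation trajectory.

    ``correlation`` is the planted residue–residue motion correlation
    (symmetric PSD, unit diagonal); fluctuations are isotropic per residue
    with one scalar correlation structure shared by the three axes, so the
    measured Calpha correlation converges to the planted matrix.
    """

    topology: Structure
    correlation: np.ndarray
    amplitude: float = 0.25
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        c = self.correlation
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("correlation must have unit diagonal")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def simulate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Sample frames = reference + correlated Gaussian displacements.

    Displacements are drawn per axis from N(0, amplitude^2 * C) across
    residues; all heavy atoms of a residue move rigidly with its Calpha, so
    contact persistence is controlled by the reference geometry.
    """
    top = spec.topology
    residues = top.residues(hetero=False)
    r = len(residues)
    if spec.correlation.shape[0] != r:
        raise ValueError(
            f"correlation is {spec.correlation.shape[0]}x… but topology has {r} residues"
        )
    evals, evecs = np.linalg.eigh(spec.correlation)
    if evals.min() < -1e-8:
        raise ValueError(f"planted correlation is not PSD (min eigenvalue {evals.min():.2e})")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T

    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_frames, 3, r))
    disp = spec.amplitude * (z @ root.T)  # (F, 3, R)

    res_index = {res: k for k, res in enumerate(residues)}
    atom_res = np.array([res_index[a.residue] for a in top.atoms])
    ref = top.xyz(0)
    frames = ref[None] + np.transpose(disp, (0, 2, 1))[:, atom_res, :]
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# contact-graph embedding and the bottleneck system


_EDGE_DIST = 10.0
_NONEDGE_MIN = 12.5
_ARM = 3.3  # arm-atom extension toward each designed partner


def _embed_contact_graph(
    n: int,
    edges: list[tuple[int, int]],
    seed: int,
    max_restarts: int = 20,
) -> np.ndarray:
    """3-D node positions with designed pairs at 10 A and others >= 12.5 A."""
    edge_set = {(min(i, j), max(i, j)) for i, j in edges}
    iu, ju = np.triu_indices(n, k=1)
    is_edge = np.array([(i, j) in edge_set for i, j in zip(iu, ju)])
    rng = np.random.default_rng(seed)

    def loss_grad(flat: np.ndarray) -> tuple[float, np.ndarray]:
        x = flat.reshape(n, 3)
        diff = x[iu] - x[ju]
        d = np.linalg.norm(diff, axis=1)
        d = np.maximum(d, 1e-9)
        resid = np.where(
            is_edge, d - _EDGE_DIST, np.minimum(d - (_NONEDGE_MIN + 0.5), 0.0)
        )
        val = float(np.sum(resid**2))
        coef = (2.0 * resid / d)[:, None] * diff
        grad = np.zeros((n, 3))
        np.add.at(grad, iu, coef)
        np.add.at(grad, ju, -coef)
        return val, grad.ravel()

    for _ in range(max_restarts):
        x0 = rng.uniform(-1, 1, (n, 3)) * 6.0 * n ** (1 / 3)
        res = minimize(loss_grad, x0.ravel(), jac=True, method="L-BFGS-B")
        x = res.x.reshape(n, 3)
        d = np.linalg.norm(x[iu] - x[ju], axis=1)
        ok = np.all(np.abs(d[is_edge] - _EDGE_DIST) < 0.5) and np.all(
            d[~is_edge] >= _NONEDGE_MIN
        )
        if ok:
            return x
    raise RuntimeError("could not embed the designed contact graph in 3-D")


def contact_topology(
    n: int,
    edges: list[tuple[int, int]],
    seed: int = 0,
    chain: str = "A",
) -> Structure:
    """A topology realising exactly the designed residue contact graph.

    Each residue gets a CA atom at its embedded position plus one arm atom
    extended toward every designed partner, so designed pairs have heavy
    atoms ~3.4 A apart (well inside the 4.5 A persistence cutoff) and all
    other pairs stay beyond it.  Residue numbers are spaced by two so the
    consecutive-residue edge exclusion never interferes with designed
    contacts.
    """
    centers = _embed_contact_graph(n, edges, seed)
    partners: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        partners[i].append(j)
        partners[j].append(i)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for i in range(n):
        resnum = 2 * (i + 1)
        atoms.append(Atom(chain, resnum, "GLY", "CA", "C"))
        coords.append(centers[i])
        for k, j in enumerate(sorted(partners[i])):
            u = centers[j] - centers[i]
            u = u / np.linalg.norm(u)
            atoms.append(Atom(chain, resnum, "GLY", f"C{k + 1}", "C"))
            coords.append(centers[i] + _ARM * u)
    return Structure(atoms, np.asarray(coords)[None])


def make_bottleneck_system(
    seed: int = 0,
    blob_size: int = 8,
    n_detour: int = 6,
    n_frames: int = 2000,
    amplitude: float = 0.25,
) -> tuple[TrajectorySpec, dict]:
    """Trajectory spec whose network funnels communication through one residue.

    Two modules ("blobs") of strongly co-moving residues are joined by a
    single bridge residue touching two hub residues of each blob, plus a
    long, weakly correlated detour path that keeps the network connected
    when the bridge is removed.  All shortest inter-module paths run through
    the bridge, so it attains the top betweenness and, because its removal
    forces traffic onto the expensive detour, the top delta path length.
    """
    b = blob_size
    blob1 = list(range(b))
    blob2 = list(range(b, 2 * b))
    bridge = 2 * b
    detour = list(range(2 * b + 1, 2 * b + 1 + n_detour))
    n = 2 * b + 1 + n_detour

    edges: list[tuple[int, int]] = []
    for blob in (blob1, blob2):
        for k in range(len(blob)):  # ring contacts inside each blob
            edges.append((blob[k], blob[(k + 1) % len(blob)]))
    hubs1, hubs2 = (blob1[0], blob1[1]), (blob2[0], blob2[1])
    for h in (*hubs1, *hubs2):
        edges.append((h, bridge))
    chain = [blob1[b // 2], *detour, blob2[b // 2]]  # far-side detour path
    for u, v in zip(chain[:-1], chain[1:]):
        edges.append((u, v))

    # factor-model correlation: PSD by construction, unit diagonal
    rho, a_bridge, c_detour = 0.7, 0.6, 0.35
    load = np.zeros((n, 2))
    load[blob1, 0] = math.sqrt(rho)
    load[blob2, 1] = math.sqrt(rho)
    load[bridge] = a_bridge
    load[detour] = c_detour
    corr = load @ load.T
    np.fill_diagonal(corr, 1.0)

    topology = contact_topology(n, edges, seed=seed)
    residues = topology.residues(hetero=False)
    spec = TrajectorySpec(
        topology=topology,
        correlation=corr,
        amplitude=amplitude,
        n_frames=n_frames,
        seed=seed,
    )
    manifest = {
        "seed": seed,
        "bridge_node": f"{residues[bridge][0]}:{residues[bridge][1]}",
        "blob1": [f"{residues[i][0]}:{residues[i][1]}" for i in blob1],
        "blob2": [f"{residues[i][0]}:{residues[i][1]}" for i in blob2],
        "detour": [f"{residues[i][0]}:{residues[i][1]}" for i in detour],
        "edges": sorted({(min(i, j), max(i, j)) for i, j in edges}),
        "correlation": corr.tolist(),
    }
    return spec, manifest


# ---------------------------------------------------------------------------
# Potts-model MSA sampling


@dataclass
class PottsSpec:
    """Recipe for a pairwise-coupled (Potts) alignment.

    ``coupled_pairs`` lists ``(i, j, strength)``: a coupling energy added
    when columns i and j carry the same amino acid (a Potts ferromagnet on
    the 20-letter alphabet), which induces strong covariation at the planted
    pairs.  Gaps are inserted independently afterwards with ``gap_prob``.
    """

    L: int = 30
    M: int = 2000
    coupled_pairs: list[tuple[int, int, float]] = dataclass_field(default_factory=list)
    fields: np.ndarray | None = None  # (L, 20) local biases, optional
    gap_prob: float = 0.0
    sweeps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for i, j, s in self.coupled_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L) or i == j:
                raise ValueError(f"bad coupled pair ({i}, {j})")
            if abs(i - j) < 2:
                raise ValueError("coupled pairs must be >= 2 columns apart")
            if not np.isfinite(s):
                raise ValueError("coupling strength must be finite")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate coupled pair {key}")
            seen.add(key)
        if self.sweeps < 1:
            raise ValueError("need at least one Gibbs sweep")
        if not 0.0 <= self.gap_prob < 1.0:
            raise ValueError("gap_prob must be in [0, 1)")


def sample_potts_msa(spec: PottsSpec) -> tuple[Alignment, dict]:
    """Gibbs-sample M sequences from the pairwise model with planted couplings.

    Each sequence is an independent Markov chain (all chains are swept in
    parallel); ``spec.sweeps`` full sweeps of single-site heat-bath updates
    serve as burn-in before the final state is taken as the sample.
    """
    rng = np.random.default_rng(spec.seed)
    n_aa = 20
    fields = (
        np.zeros((spec.L, n_aa)) if spec.fields is None else np.asarray(spec.fields, float)
    )
    if fields.shape != (spec.L, n_aa):
        raise ValueError(f"fields must have shape ({spec.L}, {n_aa})")

    partners: dict[int, list[tuple[int, float]]] = {i: [] for i in range(spec.L)}
    for i, j, s in spec.coupled_pairs:
        partners[i].append((j, s))
        partners[j].append((i, s))

    state = rng.integers(0, n_aa, size=(spec.M, spec.L))
    rows = np.arange(spec.M)
    for _ in range(spec.sweeps):
        for i in range(spec.L):
            logits = np.broadcast_to(fields[i], (spec.M, n_aa)).copy()
            for j, s in partners[i]:
                logits[rows, state[:, j]] += s
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((spec.M, 1))
            state[:, i] = (p.cumsum(axis=1) < u).sum(axis=1)

    codes = (state + 1).astype(np.int8)  # shift: 0 is the gap state
    if spec.gap_prob > 0:
        gaps = rng.random(codes.shape) < spec.gap_prob
        codes[gaps] = 0
    ids = [f"synth_{k:05d}" for k in range(spec.M)]
    aln = Alignment(ids, codes)
    manifest = {
        "seed": spec.seed,
        "L": spec.L,
        "M": spec.M,
        "coupled_pairs": [(int(i), int(j), float(s)) for i, j, s in spec.coupled_pairs],
        "gap_prob": spec.gap_prob,
        "sweeps": spec.sweeps,
    }
    return aln, manifest
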