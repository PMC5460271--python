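"""Dynamical residue networks from trajectories.

Nodes are residues; two nonconsecutive residues are linked when a pair of
heavy atoms, one from each residue, is within 4.5 A in at least 75 % of the
frames (contact persistence) and their Calpha motion correlation is
positive.  Edge weights are ``W_ij = -log(C_ij)`` (natural log), so strongly
co-moving residues are "close" in the network.  Anticorrelated pairs
(C_ij <= 0) carry no edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueKey, Structure, StructureError, read_models

__all__ = [
    "Trajectory",
    "MotionCorrelation",
    "motion_correlation",
    "contact_persistence",
    "build_network",
    "network_from_trajectory",
    "read_trajectory",
    "network_to_json",
]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology."""

    topology: Structure  # coords of the topology itself are ignored
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def sliced(self, start: int = 0, stop: int | None = None) -> "Trajectory":
        """Frame-range selection (e.g. to drop an equilibration prefix)."""
        return Trajectory(self.topology, self.frames[start:stop], self.frame_interval)


@dataclass
class MotionCorrelation:
    residues: list[ResidueKey]
    matrix: np.ndarray


def read_trajectory(pdb_text: str) -> Trajectory:
    """Read a multi-model PDB as a trajectory (models are frames)."""
    s = read_models(pdb_text)
    if s.n_models < 2:
        raise StructureError("trajectory needs >= 2 MODEL records")
    return Trajectory(s.model(0), s.coords)


def _ca_indices(top: Structure) -> tuple[list[ResidueKey], np.ndarray]:
    residues = top.residues(hetero=False)
    idx = {}
    for i, a in enumerate(top.atoms):
        if not a.is_hetero and a.name == "CA":
            idx[a.residue] = i
    missing = [r for r in residues if r not in idx]
    if missing:
        raise StructureError(f"residues without a CA atom: {missing[:5]}")
    return residues, np.array([idx[r] for r in residues], dtype=int)


def motion_correlation(t: Trajectory) -> MotionCorrelation:
    """Normalised covariance of Calpha displacement vectors over frames.

    ``C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)`` with
    ``dr_i(t) = r_i(t) - <r_i>``; the diagonal is exactly 1.
    """
    residues, ca = _ca_indices(t.topology)
    x = t.frames[:, ca, :]  # (F, R, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", dx, dx) / t.n_frames
    var = np.diag(cov).copy()
    frozen = np.flatnonzero(var <= 0)
    if frozen.size:
        names = [residues[i] for i in frozen[:5]]
        raise ValueError(f"zero-variance (frozen) residues: {names}")
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return MotionCorrelation(residues, c)


def _consecutive_mask(residues: list[ResidueKey]) -> np.ndarray:
    """True where two residues are sequence-consecutive within one chain."""
    n = len(residues)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        ci, ni = residues[i][0], residues[i][1]
        for j in range(i + 1, n):
            if residues[j][0] == ci and abs(residues[j][1] - ni) == 1:
                mask[i, j] = mask[j, i] = True
    return mask


def contact_persistence(
    t: Trajectory,
    cutoff: float = 4.5,
    min_fraction: float = 0.75,
) -> tuple[list[ResidueKey], np.ndarray]:
    """Boolean matrix of persistent residue contacts.

    A pair is persistent when its minimum heavy-atom distance is below
    ``cutoff`` in at least ``min_fraction`` of the frames.  Sequence-
    consecutive pairs of the same chain are never persistent (they carry no
    network edge).
    """
    if t.n_frames < 2:
        raise ValueError("persistence needs >= 2 frames")
    top = t.topology
    residues = top.residues(hetero=False)
    res_index = {r: i for i, r in enumerate(residues)}
    atom_res = np.array(
        [res_index.get(a.residue, -1) if not a.is_hetero else -1 for a in top.atoms]
    )
    keep = np.flatnonzero(atom_res >= 0)
    rid = atom_res[keep]
    n = len(residues)
    counts = np.zeros((n, n), dtype=np.int64)
    for f in range(t.n_frames):
        xyz = t.frames[f, keep]
        tree = cKDTree(xyz)
        frame_contacts = np.zeros((n, n), dtype=bool)
        for i, j in tree.query_pairs(cutoff):
            ri, rj = rid[i], rid[j]
            if ri != rj:
                frame_contacts[ri, rj] = frame_contacts[rj, ri] = True
        counts += frame_contacts
    persistent = counts >= min_fraction * t.n_frames - 1e-9
    persistent &= ~_consecutive_mask(residues)
    np.fill_diagonal(persistent, False)
    return residues, persistent


def build_network(
    c: MotionCorrelation,
    persistent: np.ndarray,
) -> nx.Graph:
    """Weighted residue network: edges for persistent, positively correlated pairs.

    Edge weight is ``-log(C_ij)`` (natural log); the raw correlation is kept
    as an edge attribute.  Node keys are ``"<chain>:<resnum>"`` strings with
    residue metadata as attributes.
    """
    persistent = np.asarray(persistent, dtype=bool)
    if persistent.shape != (len(c.residues),) * 2:
        raise ValueError("correlation and persistence matrices index different residues")
    g = nx.Graph()
    labels = [f"{r[0]}:{r[1]}" for r in c.residues]
    for lab, (chain, resnum, resname) in zip(labels, c.residues):
        g.add_node(lab, chain=chain, resnum=int(resnum), resname=resname)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not persistent[i, j]:
                continue
            cij = float(c.matrix[i, j])
            if cij <= 0.0:
                continue  # anticorrelated or uncorrelated pairs carry no edge
            g.add_edge(
                labels[i],
                labels[j],
                weight=float(-np.log(cij)),
                correlation=cij,
            )
    return g


def network_from_trajectory(
    t: Trajectory,
    contact_cutoff: float = 4.5,
    min_fraction: float = 0.75,
    frame_start: int = 0,
) -> nx.Graph:
    """Convenience wrapper: correlation + persistence -> weighted network."""
    t = t.sliced(frame_start)
    corr = motion_correlation(t)
    residues, persistent = contact_persistence(t, cutoff=contact_cutoff, min_fraction=min_fraction)
    if residues != corr.residues:
        raise ValueError("inconsistent residue ordering")
    return build_network(corr, persistent)


def network_to_json(g: nx.Graph) -> str:
    """Node-link JSON serialisation of the network."""
    payload = nx.node_link_data(g, edges="links")
    return json.dumps(payload, indent=1, sort_keys=True)
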