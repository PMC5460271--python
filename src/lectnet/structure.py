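"""Protein structures, solvent accessibility and residue classification.

A residue of a dimer is called *interface* when it is solvent exposed in the
isolated monomer but no longer exposed in the complex, *surface* when it is
exposed in both, and *interior* when it is buried already in the monomer.
Ligand-binding residues (e.g. the mannose pocket of a bulb-type lectin) are
detected by a heavy-atom distance criterion and take precedence over the
other categories, while also being reported as an independent flag.

Solvent-accessible surface area (SASA) is computed with Shrake–Rupley
sphere sampling; relative SASA divides the absolute per-residue area by a
residue-type reference maximum (bundled table, configurable).
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "SasaProfile",
    "ResidueClassification",
    "ContactPair",
    "StructureError",
    "read_structure",
    "read_models",
    "compute_sasa",
    "classify_residues",
    "find_interface_pairs",
    "find_ligand_contacts",
    "load_sasa_tables",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ResidueKey = tuple[str, int, str]  # (chain id, residue number, residue name)


class StructureError(ValueError):
    """Raised for unparseable or structurally invalid input."""


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    is_hetero: bool = False

    @property
    def residue(self) -> ResidueKey:
        return (self.chain, self.resnum, self.resname)


@dataclass
class Structure:
    """Heavy atoms of one or more models sharing a single topology.

    ``coords`` has shape ``(n_models, n_atoms, 3)`` in Angstrom.
    """

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1] != len(self.atoms):
            raise StructureError(
                f"coordinate array for {self.coords.shape[1]} atoms does not "
                f"match {len(self.atoms)} atom records"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        seen: set[tuple[ResidueKey, str]] = set()
        for a in self.atoms:
            key = (a.residue, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key} within one model")
            seen.add(key)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def model(self, index: int) -> "Structure":
        return Structure(self.atoms, self.coords[index][None])

    def xyz(self, model: int = 0) -> np.ndarray:
        return self.coords[model]

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def residues(self, hetero: bool | None = None) -> list[ResidueKey]:
        """Ordered residue keys; ``hetero`` filters ligand (True) or protein (False)."""
        out: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        for a in self.atoms:
            if hetero is not None and a.is_hetero is not hetero:
                continue
            if a.residue not in seen:
                seen.add(a.residue)
                out.append(a.residue)
        return out

    def atom_indices(self, chain: str | None = None, hetero: bool | None = None) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (chain is None or a.chain == chain)
            and (hetero is None or a.is_hetero is hetero)
        ]
        return np.asarray(idx, dtype=int)

    def residue_atom_indices(self, hetero: bool | None = None) -> dict[ResidueKey, np.ndarray]:
        groups: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            if hetero is not None and a.is_hetero is not hetero:
                continue
            groups.setdefault(a.residue, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def select(self, indices: Sequence[int]) -> "Structure":
        indices = np.asarray(indices, dtype=int)
        return Structure([self.atoms[i] for i in indices], self.coords[:, indices])

    def select_chains(self, chains: Iterable[str]) -> "Structure":
        chains = set(chains)
        idx = [i for i, a in enumerate(self.atoms) if a.chain in chains]
        if not idx:
            raise StructureError(f"no atoms in chains {sorted(chains)}")
        return self.select(idx)


@dataclass
class SasaProfile:
    """Per-residue absolute (A^2) and relative solvent accessibility."""

    residues: list[ResidueKey]
    absolute: np.ndarray
    relative: np.ndarray
    probe_radius: float = 1.4

    def as_dict(self) -> dict[ResidueKey, tuple[float, float]]:
        return {
            r: (float(a), float(s))
            for r, a, s in zip(self.residues, self.absolute, self.relative)
        }


@dataclass
class ResidueClassification:
    residues: list[ResidueKey]
    category: list[str]  # interface / surface / interior / ligand-binding
    monomer_relative: np.ndarray
    complex_relative: np.ndarray
    ligand_binding: np.ndarray  # independent boolean flag

    def of_category(self, name: str) -> list[ResidueKey]:
        return [r for r, c in zip(self.residues, self.category) if c == name]


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    distance: float

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.distance, ndigits)


# ---------------------------------------------------------------------------
# parsing


def _parse_biopdb(pdb_text: str):
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            return parser.get_structure("input", io.StringIO(pdb_text))
    except PDBConstructionException as exc:
        raise StructureError(f"PDB parse error: {exc}") from exc
    except ValueError as exc:
        raise StructureError(f"malformed coordinate field: {exc}") from exc


def _model_to_arrays(model) -> tuple[list[Atom], np.ndarray]:
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            resname = residue.get_resname().strip()
            if resname in WATER_NAMES or hetflag == "W":
                continue
            is_het = hetflag.strip() != ""
            for atom in residue.get_unpacked_list():
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                # altloc: keep the highest-occupancy conformer only
                if atom.is_disordered() or (atom.get_altloc() or " ") != " ":
                    parent = residue[atom.get_name()]
                    if parent.is_disordered():
                        best = max(
                            parent.disordered_get_list(),
                            key=lambda a: a.get_occupancy() or 0.0,
                        )
                        if atom.get_altloc() != best.get_altloc():
                            continue
                name = atom.get_name().strip()
                key = (chain.id, resnum, resname, name)
                if any(
                    (a.chain, a.resnum, a.resname, a.name) == key for a in atoms[-30:]
                ):
                    continue  # duplicate altloc already kept
                atoms.append(
                    Atom(chain.id, resnum, resname, name, element or "C", is_het)
                )
                coords.append(np.asarray(atom.get_coord(), dtype=float))
    return atoms, np.asarray(coords, dtype=float)


def read_structure(pdb_text: str, model_index: int = 0) -> Structure:
    """Parse PDB text into a single-model heavy-atom :class:`Structure`.

    Hydrogens and waters are dropped; ligand heteroatoms are retained and
    flagged.  Raises :class:`StructureError` on malformed records or when no
    atoms survive the selection.
    """
    bio = _parse_biopdb(pdb_text)
    models = list(bio.get_models())
    if not models:
        raise StructureError("empty selection: no models in input")
    if model_index >= len(models):
        raise StructureError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    atoms, coords = _model_to_arrays(models[model_index])
    if not atoms:
        raise StructureError("empty selection: no heavy atoms after filtering")
    return Structure(atoms, coords[None])


def read_models(pdb_text: str) -> Structure:
    """Parse multi-model PDB text, stacking all models on one topology."""
    bio = _parse_biopdb(pdb_text)
    models = list(bio.get_models())
    if not models:
        raise StructureError("empty selection: no models in input")
    atoms0, coords0 = _model_to_arrays(models[0])
    if not atoms0:
        raise StructureError("empty selection: no heavy atoms after filtering")
    frames = [coords0]
    key0 = [(a.chain, a.resnum, a.resname, a.name) for a in atoms0]
    for m in models[1:]:
        atoms, coords = _model_to_arrays(m)
        key = [(a.chain, a.resnum, a.resname, a.name) for a in atoms]
        if key != key0:
            raise StructureError("models do not share one topology")
        frames.append(coords)
    return Structure(atoms0, np.stack(frames))


# ---------------------------------------------------------------------------
# SASA


def load_sasa_tables(path: str | None = None) -> tuple[dict[str, float], dict[str, float]]:
    """Return (vdW radius per element, max SASA per residue type)."""
    if path is None:
        text = resources.files("lectnet.data").joinpath("sasa_tables.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    tables = json.loads(text)
    return (
        {k.upper(): float(v) for k, v in tables["vdw_radii"].items()},
        {k.upper(): float(v) for k, v in tables["max_sasa"].items()},
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley SASA per atom (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    pts = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    out = np.empty(n)
    rmax = float(expanded.max())
    for i in range(n):
        ri = expanded[i]
        neighbors = tree.query_ball_point(coords[i], ri + rmax)
        neighbors = [j for j in neighbors if j != i]
        sphere = coords[i] + ri * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            rj = expanded[j]
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        out[i] = 4.0 * math.pi * ri * ri * exposed.mean()
    return out


def compute_sasa(
    s: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    model: int = 0,
    radii_table: Mapping[str, float] | None = None,
    max_sasa_table: Mapping[str, float] | None = None,
) -> SasaProfile:
    """Per-residue SASA of one model by Shrake–Rupley sphere sampling.

    Relative SASA divides by a residue-type reference maximum; residue types
    absent from the reference table get relative SASA ``nan`` with a warning
    (this only affects non-standard residues / ligands, which are never
    classified).
    """
    default_radii, default_max = load_sasa_tables()
    radii_table = dict(default_radii if radii_table is None else radii_table)
    max_table = dict(default_max if max_sasa_table is None else max_sasa_table)

    radii = np.empty(s.n_atoms)
    for i, a in enumerate(s.atoms):
        r = radii_table.get(a.element.upper())
        if r is None:
            raise StructureError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.chain}:{a.resnum}:{a.name})"
            )
        radii[i] = r

    per_atom = atom_sasa(s.xyz(model), radii, probe=probe, n_points=n_points)

    groups = s.residue_atom_indices()
    residues = list(groups)
    absolute = np.array([per_atom[groups[r]].sum() for r in residues])
    relative = np.empty(len(residues))
    missing: list[str] = []
    for k, res in enumerate(residues):
        ref = max_table.get(res[2].upper())
        if ref is None:
            relative[k] = np.nan
            missing.append(res[2])
        else:
            relative[k] = absolute[k] / ref
    if missing:
        warnings.warn(
            f"no reference max SASA for residue types {sorted(set(missing))}; "
            "relative SASA set to nan"
        )
    return SasaProfile(residues, absolute, relative, probe_radius=probe)


# ---------------------------------------------------------------------------
# classification and contacts


def classify_residues(
    monomer_sasa: SasaProfile,
    complex_sasa: SasaProfile,
    exposed_threshold: float = 0.20,
    ligand_contacts: Iterable[ResidueKey] = (),
) -> ResidueClassification:
    """Classify residues as interface / surface / interior / ligand-binding.

    interface: relative SASA > threshold in the monomer and <= threshold in
    the complex; surface: > threshold in both; interior: <= threshold in the
    monomer.  Ligand binding takes precedence and is also kept as an
    independent flag so the sets may overlap in downstream reports.
    """
    mono = monomer_sasa.as_dict()
    comp = complex_sasa.as_dict()
    if set(mono) != set(comp):
        only = set(mono).symmetric_difference(comp)
        raise StructureError(
            f"monomer/complex profiles cover different residues: {sorted(only)[:5]}"
        )
    ligand_set = set(ligand_contacts)
    residues = list(monomer_sasa.residues)
    cats: list[str] = []
    lig = np.zeros(len(residues), dtype=bool)
    m_rel = np.empty(len(residues))
    c_rel = np.empty(len(residues))
    for k, res in enumerate(residues):
        m_rel[k] = mono[res][1]
        c_rel[k] = comp[res][1]
        lig[k] = res in ligand_set
        if m_rel[k] > exposed_threshold and c_rel[k] <= exposed_threshold:
            cat = "interface"
        elif m_rel[k] > exposed_threshold:
            cat = "surface"
        else:
            cat = "interior"
        if lig[k]:
            cat = "ligand-binding"
        cats.append(cat)
    return ResidueClassification(residues, cats, m_rel, c_rel, lig)


def find_interface_pairs(
    complex_structure: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.0,
    model: int = 0,
) -> list[ContactPair]:
    """Cross-chain residue pairs with minimum heavy-atom distance < cutoff.

    Sorted by chain-A residue number (then chain-B number); the stored
    distance is the minimum over heavy-atom pairs, unrounded.
    """
    chains = complex_structure.chains()
    for c in (chain_a, chain_b):
        if c not in chains:
            raise StructureError(f"chain {c!r} not in structure (has {chains})")
    xyz = complex_structure.xyz(model)
    ia = complex_structure.atom_indices(chain=chain_a, hetero=False)
    ib = complex_structure.atom_indices(chain=chain_b, hetero=False)
    tree_b = cKDTree(xyz[ib])
    pairs: dict[tuple[ResidueKey, ResidueKey], float] = {}
    neighbor_lists = tree_b.query_ball_point(xyz[ia], cutoff)
    for ai, neighbors in zip(ia, neighbor_lists):
        if not neighbors:
            continue
        res_a = complex_structure.atoms[ai].residue
        for bj in neighbors:
            bi = ib[bj]
            d = float(np.linalg.norm(xyz[ai] - xyz[bi]))
            if d >= cutoff:
                continue
            res_b = complex_structure.atoms[bi].residue
            key = (res_a, res_b)
            if d < pairs.get(key, np.inf):
                pairs[key] = d
    out = [ContactPair(a, b, d) for (a, b), d in pairs.items()]
    out.sort(key=lambda p: (p.residue_a[1], p.residue_b[1]))
    return out


def find_ligand_contacts(
    s: Structure,
    ligand_names: Iterable[str],
    cutoff: float = 3.9,
    model: int = 0,
) -> set[ResidueKey]:
    """Protein residues with any heavy atom within ``cutoff`` of a ligand atom."""
    ligand_names = {n.upper() for n in ligand_names}
    xyz = s.xyz(model)
    lig_idx = [
        i
        for i, a in enumerate(s.atoms)
        if a.is_hetero and a.resname.upper() in ligand_names
    ]
    if not lig_idx:
        raise StructureError(f"no ligand residues named {sorted(ligand_names)}")
    prot_idx = s.atom_indices(hetero=False)
    tree = cKDTree(xyz[lig_idx])
    dists, _ = tree.query(xyz[prot_idx], k=1)
    out: set[ResidueKey] = set()
    for i, d in zip(prot_idx, dists):
        if d < cutoff:
            out.add(s.atoms[i].residue)
    return out


def classification_table(cls: ResidueClassification) -> "pandas.DataFrame":  # noqa: F821
    """Per-residue classification as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chain": [r[0] for r in cls.residues],
            "resnum": [r[1] for r in cls.residues],
            "resname": [r[2] for r in cls.residues],
            "rel_sasa_monomer": cls.monomer_relative,
            "rel_sasa_complex": cls.complex_relative,
            "category": cls.category,
            "ligand_binding": cls.ligand_binding,
        }
    )


def contact_table(pairs: Sequence[ContactPair]) -> "pandas.DataFrame":  # noqa: F821
    """Interface contact pairs as a DataFrame mirroring a contact-table layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chain_a": [p.residue_a[0] for p in pairs],
            "resnum_a": [p.residue_a[1] for p in pairs],
            "resname_a": [p.residue_a[2] for p in pairs],
            "chain_b": [p.residue_b[0] for p in pairs],
            "resnum_b": [p.residue_b[1] for p in pairs],
            "resname_b": [p.residue_b[2] for p in pairs],
            "distance": [p.rounded(2) for p in pairs],
        }
    )
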