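"""Protein-ligand complexes as multi-graphs.

A complex (protein P, ligand L, binding conformation C) is represented by
three graphs built from inter-atomic distances:

* ligand graph   — atoms as nodes, edges for atom pairs closer than 5.0 A,
* protein graph  — residues as nodes (alpha-carbon coordinates), edges for
  CA pairs closer than 8.0 A,
* interaction graph — bipartite residue-atom graph with edges for CA-atom
  pairs closer than 12.0 A.

All cutoffs use a strict ``<`` comparison and all graphs are stored
undirected without self-loops, edge (i, j) with i < j for the homogeneous
graphs.  Coordinates are Angstrom; indices are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

# Default distance thresholds (Angstrom)
LIGAND_CUTOFF = 5.0
PROTEIN_CUTOFF = 8.0
INTERACTION_CUTOFF = 12.0

SCHEMA_VERSION = "2024.1"

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")  # + "other"
HYBRIDIZATIONS = ("SP", "SP2", "SP3")  # + "other"
MAX_DEGREE = 5
N_RBF = 16

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Kyte-Doolittle hydropathy, side-chain charge class at pH 7, residue mass (Da)
_RESIDUE_PROPS = {
    "ALA": (1.8, 0, 89.1), "ARG": (-4.5, 1, 174.2), "ASN": (-3.5, 0, 132.1),
    "ASP": (-3.5, -1, 133.1), "CYS": (2.5, 0, 121.2), "GLN": (-3.5, 0, 146.2),
    "GLU": (-3.5, -1, 147.1), "GLY": (-0.4, 0, 75.1), "HIS": (-3.2, 0, 155.2),
    "ILE": (4.5, 0, 131.2), "LEU": (3.8, 0, 131.2), "LYS": (-3.9, 1, 146.2),
    "MET": (1.9, 0, 149.2), "PHE": (2.8, 0, 165.2), "PRO": (-1.6, 0, 115.1),
    "SER": (-0.8, 0, 105.1), "THR": (-0.7, 0, 119.1), "TRP": (-0.9, 0, 204.2),
    "TYR": (-1.3, 0, 181.2), "VAL": (4.2, 0, 117.1),
}

BOND_ORDERS = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")  # + "none"

ATOM_FEATURE_LENGTH = len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + 1 + 1 + 1 + len(HYBRIDIZATIONS) + 1
RESIDUE_FEATURE_LENGTH = len(STANDARD_RESIDUES) + 1 + 3
LIGAND_EDGE_FEATURE_LENGTH = N_RBF + len(BOND_ORDERS) + 1
PROTEIN_EDGE_FEATURE_LENGTH = N_RBF
INTERACTION_EDGE_FEATURE_LENGTH = N_RBF


class ParseError(ValueError):
    """A structure file could not be read."""


class EmptyStructureError(ValueError):
    """A parsed structure contained no usable atoms/residues."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class AtomRecord:
    """A heavy atom of the ligand: element, coordinate (A) and feature vector."""

    index: int
    element: str
    coord: np.ndarray
    features: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.index}: coord must be 3 finite values")
        if self.features is None:
            self.features = featurize_atom(self.element)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (ATOM_FEATURE_LENGTH,):
            raise ValueError(
                f"atom {self.index}: feature length {self.features.shape} != "
                f"({ATOM_FEATURE_LENGTH},)"
            )


@dataclass
class ResidueRecord:
    """A protein residue represented by its alpha-carbon coordinate."""

    index: int
    residue_name: str
    ca_coord: np.ndarray
    features: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        if self.ca_coord.shape != (3,) or not np.all(np.isfinite(self.ca_coord)):
            raise ValueError(f"residue {self.index}: ca_coord must be 3 finite values")
        if self.residue_name not in STANDARD_RESIDUES:
            self.residue_name = "UNK"
        if self.features is None:
            self.features = featurize_residue(self.residue_name)
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (RESIDUE_FEATURE_LENGTH,):
            raise ValueError(
                f"residue {self.index}: feature length mismatch "
                f"({self.features.shape} != ({RESIDUE_FEATURE_LENGTH},))"
            )


@dataclass
class ComplexStructure:
    """A (protein, ligand, conformation) triple; coordinates embed the pose."""

    protein: list[ResidueRecord]
    ligand: list[AtomRecord]
    protein_id: str = ""
    ligand_id: str = ""
    pose_rank: int | None = None
    bonds: dict[frozenset, str] | None = None  # ligand connectivity, optional

    def __post_init__(self):
        if not self.ligand:
            raise EmptyStructureError("ligand has no atoms")
        if not self.protein:
            raise EmptyStructureError("protein has no residues")


@dataclass
class LigandGraph:
    nodes: list[AtomRecord]
    edges: list[tuple[int, int]]
    edge_features: np.ndarray
    cutoff: float = LIGAND_CUTOFF


@dataclass
class ProteinGraph:
    nodes: list[ResidueRecord]
    edges: list[tuple[int, int]]
    edge_features: np.ndarray
    cutoff: float = PROTEIN_CUTOFF


@dataclass
class InteractionGraph:
    """Bipartite residue-atom contact graph; edge (i, j) = (residue, atom)."""

    residue_count: int
    atom_count: int
    edges: list[tuple[int, int]]
    edge_features: np.ndarray
    cutoff: float = INTERACTION_CUTOFF


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def _one_hot(value, choices) -> np.ndarray:
    """One-hot with a trailing 'other' slot; unknown values map there."""
    v = np.zeros(len(choices) + 1)
    try:
        v[list(choices).index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def featurize_atom(
    element: str,
    degree: int = 0,
    formal_charge: int = 0,
    aromatic: bool = False,
    in_ring: bool = False,
    hybridization: str = "other",
) -> np.ndarray:
    """Atom feature vector: element, degree, charge, aromatic/ring flags,
    hybridization.  Unknown categories fall into an explicit 'other' slot."""
    deg = np.zeros(MAX_DEGREE + 1)
    deg[min(max(int(degree), 0), MAX_DEGREE)] = 1.0
    return np.concatenate(
        [
            _one_hot(element, ELEMENTS),
            deg,
            [float(formal_charge)],
            [1.0 if aromatic else 0.0],
            [1.0 if in_ring else 0.0],
            _one_hot(hybridization, HYBRIDIZATIONS),
        ]
    )


def featurize_residue(residue_name: str) -> np.ndarray:
    """Residue feature vector: 20+1 one-hot, hydropathy, charge class,
    scaled molecular weight."""
    hydro, charge, mw = _RESIDUE_PROPS.get(residue_name, (0.0, 0, 110.0))
    return np.concatenate(
        [_one_hot(residue_name, STANDARD_RESIDUES), [hydro, float(charge), mw / 100.0]]
    )


def rbf_expand(distance: float, cutoff: float, n_centers: int = N_RBF) -> np.ndarray:
    """Gaussian radial-basis expansion of a distance on [0, cutoff].

    Centers are evenly spaced; the bandwidth equals the center spacing, so a
    distance exactly at a center contributes 1.0 in that basis slot.
    """
    centers = np.linspace(0.0, cutoff, n_centers)
    gamma = 1.0 / (centers[1] - centers[0]) ** 2
    return np.exp(-gamma * (distance - centers) ** 2)


def featurize_ligand_edge(
    distance: float,
    bond_order: str | None = None,
    cutoff: float = LIGAND_CUTOFF,
) -> np.ndarray:
    bond = _one_hot(bond_order if bond_order is not None else "none", BOND_ORDERS)
    return np.concatenate([rbf_expand(distance, cutoff), bond])


def featurize_protein_edge(distance: float, cutoff: float = PROTEIN_CUTOFF) -> np.ndarray:
    return rbf_expand(distance, cutoff)


def featurize_interaction_edge(
    distance: float, cutoff: float = INTERACTION_CUTOFF
) -> np.ndarray:
    return rbf_expand(distance, cutoff)


FEATURE_SCHEMA = {
    "version": SCHEMA_VERSION,
    "atom_length": ATOM_FEATURE_LENGTH,
    "residue_length": RESIDUE_FEATURE_LENGTH,
    "ligand_edge_length": LIGAND_EDGE_FEATURE_LENGTH,
    "protein_edge_length": PROTEIN_EDGE_FEATURE_LENGTH,
    "interaction_edge_length": INTERACTION_EDGE_FEATURE_LENGTH,
    "elements": ELEMENTS,
    "residues": STANDARD_RESIDUES,
    "n_rbf": N_RBF,
}


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def parse_ligand(
    path: str | Path,
    fmt: str | None = None,
    keep_hydrogens: bool = False,
    with_bonds: bool = False,
):
    """Read a ligand structure (SDF or MOL2) into AtomRecords.

    Hydrogens are dropped by default (docked poses frequently omit them).
    With ``with_bonds=True`` also returns a {frozenset({i, j}): order} map of
    file-provided connectivity between the retained heavy atoms.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper() or "SDF"
    fmt = fmt.upper()
    if fmt == "SDF":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier), None)
    elif fmt == "MOL2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise ParseError(f"unsupported ligand format: {fmt}")
    if mol is None:
        raise ParseError(f"could not parse {fmt} file {path}")
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # keep raw perception if sanitization fails
        mol.UpdatePropertyCache(strict=False)
    conf = mol.GetConformer()

    records: list[AtomRecord] = []
    keep_map: dict[int, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "H" and not keep_hydrogens:
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        hyb = str(atom.GetHybridization())
        records.append(
            AtomRecord(
                index=len(records),
                element=sym,
                coord=np.array([pos.x, pos.y, pos.z]),
                features=featurize_atom(
                    sym,
                    degree=sum(
                        1
                        for nb in atom.GetNeighbors()
                        if keep_hydrogens or nb.GetSymbol() != "H"
                    ),
                    formal_charge=atom.GetFormalCharge(),
                    aromatic=atom.GetIsAromatic(),
                    in_ring=atom.IsInRing(),
                    hybridization=hyb if hyb in HYBRIDIZATIONS else "other",
                ),
            )
        )
        keep_map[atom.GetIdx()] = records[-1].index
    if not records:
        raise EmptyStructureError(f"{path}: no heavy atoms")
    if not with_bonds:
        return records
    bonds: dict[frozenset, str] = {}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in keep_map and j in keep_map:
            bonds[frozenset((keep_map[i], keep_map[j]))] = str(bond.GetBondType())
    return records, bonds


def parse_protein(path: str | Path) -> list[ResidueRecord]:
    """Read a PDB file into ResidueRecords, one per residue with a CA atom.

    Residues are ordered by (chain, residue number); residues lacking a CA
    atom are skipped with a warning; HETATM records are ignored.  For
    disordered atoms the alternate location with the smallest altloc id is
    kept, deterministically.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Atom import DisorderedAtom

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protein", str(path))
    except Exception as exc:
        raise ParseError(f"could not parse PDB file {path}: {exc}") from exc

    records: list[ResidueRecord] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise EmptyStructureError(f"{path}: no models with ATOM records")
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # HETATM / water
                continue
            if "CA" not in residue:
                logger.warning(
                    "residue %s %s in chain %s has no CA atom; skipped",
                    residue.get_resname(), residue.id[1], chain.id,
                )
                continue
            ca = residue["CA"]
            if isinstance(ca, DisorderedAtom):
                altloc = sorted(ca.disordered_get_id_list())[0]
                ca = ca.disordered_get(altloc)
            name = residue.get_resname().strip()
            if name not in STANDARD_RESIDUES:
                name = "UNK"
            records.append(
                ResidueRecord(
                    index=len(records),
                    residue_name=name,
                    ca_coord=np.asarray(ca.get_coord(), dtype=float),
                )
            )
    if not records:
        raise EmptyStructureError(f"{path}: no residues with CA atoms")
    return records


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _distance_edges(coords: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Unordered pairs (i, j), i < j, with Euclidean distance strictly below
    cutoff; sorted lexicographically."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinate")
    d = cdist(coords, coords)
    ii, jj = np.nonzero(np.triu(d < cutoff, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def build_ligand_graph(
    atoms: list[AtomRecord],
    cutoff: float = LIGAND_CUTOFF,
    bonds: dict[frozenset, str] | None = None,
) -> LigandGraph:
    """Ligand graph: edges between heavy-atom pairs closer than `cutoff`."""
    if not atoms:
        raise EmptyStructureError("ligand graph needs at least one atom")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.array([a.coord for a in atoms])
    edges = _distance_edges(coords, cutoff)
    feats = np.zeros((len(edges), LIGAND_EDGE_FEATURE_LENGTH))
    for k, (i, j) in enumerate(edges):
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        order = bonds.get(frozenset((i, j))) if bonds else None
        feats[k] = featurize_ligand_edge(dist, order, cutoff)
    return LigandGraph(nodes=atoms, edges=edges, edge_features=feats, cutoff=cutoff)


def build_protein_graph(
    residues: list[ResidueRecord], cutoff: float = PROTEIN_CUTOFF
) -> ProteinGraph:
    """Protein graph: edges between CA pairs closer than `cutoff`."""
    if not residues:
        raise EmptyStructureError("protein graph needs at least one residue")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.array([r.ca_coord for r in residues])
    edges = _distance_edges(coords, cutoff)
    feats = np.zeros((len(edges), PROTEIN_EDGE_FEATURE_LENGTH))
    for k, (i, j) in enumerate(edges):
        feats[k] = featurize_protein_edge(
            float(np.linalg.norm(coords[i] - coords[j])), cutoff
        )
    return ProteinGraph(nodes=residues, edges=edges, edge_features=feats, cutoff=cutoff)


def build_interaction_graph(
    residues: list[ResidueRecord],
    atoms: list[AtomRecord],
    cutoff: float = INTERACTION_CUTOFF,
) -> InteractionGraph:
    """Bipartite residue-atom graph: edges where CA-atom distance < cutoff.

    An empty edge set is allowed here; callers decide how to treat
    contact-free complexes.
    """
    if not residues or not atoms:
        raise EmptyStructureError("interaction graph needs residues and atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rc = np.array([r.ca_coord for r in residues])
    ac = np.array([a.coord for a in atoms])
    if not (np.all(np.isfinite(rc)) and np.all(np.isfinite(ac))):
        raise ValueError("non-finite coordinate")
    d = cdist(rc, ac)
    ii, jj = np.nonzero(d < cutoff)
    edges = list(zip(ii.tolist(), jj.tolist()))
    feats = np.zeros((len(edges), INTERACTION_EDGE_FEATURE_LENGTH))
    for k, (i, j) in enumerate(edges):
        feats[k] = featurize_interaction_edge(float(d[i, j]), cutoff)
    return InteractionGraph(
        residue_count=len(residues),
        atom_count=len(atoms),
        edges=edges,
        edge_features=feats,
        cutoff=cutoff,
    )


def pocket_residues(
    residues: list[ResidueRecord],
    atoms: list[AtomRecord],
    cutoff: float = INTERACTION_CUTOFF,
) -> list[ResidueRecord]:
    """Residues whose CA lies within `cutoff` of any ligand atom (re-indexed).

    Interactions beyond the interaction cutoff never enter the model, so the
    protein graph is restricted to this pocket by default.
    """
    rc = np.array([r.ca_coord for r in residues])
    ac = np.array([a.coord for a in atoms])
    keep = np.nonzero((cdist(rc, ac) < cutoff).any(axis=1))[0]
    return [
        ResidueRecord(
            index=n,
            residue_name=residues[i].residue_name,
            ca_coord=residues[i].ca_coord,
            features=residues[i].features,
        )
        for n, i in enumerate(keep.tolist())
    ]


def build_complex_graphs(
    cs: ComplexStructure,
    ligand_cutoff: float = LIGAND_CUTOFF,
    protein_cutoff: float = PROTEIN_CUTOFF,
    interaction_cutoff: float = INTERACTION_CUTOFF,
    pocket_only: bool = True,
) -> tuple[LigandGraph, ProteinGraph, InteractionGraph]:
    """Build all three graphs for a complex.

    With ``pocket_only`` (default) the protein is first truncated to residues
    within the interaction cutoff of the ligand; set False for the full chain.
    """
    residues = (
        pocket_residues(cs.protein, cs.ligand, interaction_cutoff)
        if pocket_only
        else cs.protein
    )
    if not residues:
        residues = cs.protein  # no pocket contact: fall back to full chain
    lg = build_ligand_graph(cs.ligand, ligand_cutoff, bonds=cs.bonds)
    pg = build_protein_graph(residues, protein_cutoff)
    ig = build_interaction_graph(residues, cs.ligand, interaction_cutoff)
    return lg, pg, ig


# ---------------------------------------------------------------------------
# On-disk graph bundle
# ---------------------------------------------------------------------------


def save_graph_bundle(
    path: str | Path,
    lg: LigandGraph,
    pg: ProteinGraph,
    ig: InteractionGraph,
    metadata: dict | None = None,
) -> None:
    """Serialize the three graphs of one complex into a single .npz bundle."""
    meta = {"schema": FEATURE_SCHEMA["version"]}
    meta.update(metadata or {})
    np.savez_compressed(
        path,
        ligand_features=np.array([a.features for a in lg.nodes]),
        ligand_coords=np.array([a.coord for a in lg.nodes]),
        ligand_edges=np.array(lg.edges, dtype=np.int64).reshape(-1, 2),
        ligand_edge_features=lg.edge_features,
        protein_features=np.array([r.features for r in pg.nodes]),
        protein_coords=np.array([r.ca_coord for r in pg.nodes]),
        protein_edges=np.array(pg.edges, dtype=np.int64).reshape(-1, 2),
        protein_edge_features=pg.edge_features,
        interaction_edges=np.array(ig.edges, dtype=np.int64).reshape(-1, 2),
        interaction_edge_features=ig.edge_features,
        cutoffs=np.array([lg.cutoff, pg.cutoff, ig.cutoff]),
        metadata=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
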