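"""Synthetic protein-ligand complexes and bioassay collections.

The generator emulates the statistical structure the pre-training framework
assumes, at desk scale and with full provenance:

* bioassays of varying size, each with a per-assay systematic label offset
  (label noise: values across assays carry different baselines),
* two measurement-type families with a systematic shift between IC50 and
  Ki/Kd values (label variety),
* 3D complexes whose true affinity is a planted linear function of the
  number of residue-atom contacts within the interaction cutoff, so both
  regression and within-assay ranking are recoverable from structure alone:

      pAff = intercept + slope * contacts + b_assay + delta_type * 1[IC50] + eps
      value_nM = 10 ** (9 - pAff)

Affinity is planted on the contact count — the one structural quantity the
encoder provably sees — rather than on chemistry, so recovery isolates the
learning framework from featurization choices.  Emitted files are minimal
standards-compliant PDB and SDF V2000.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .bioassay_data import AffinityRecord, write_affinity_table
from .complex_graphs import (
    STANDARD_RESIDUES,
    AtomRecord,
    ComplexStructure,
    ResidueRecord,
    build_interaction_graph,
)

LIGAND_ELEMENTS = ("C", "C", "C", "C", "N", "O")  # carbon-rich draws


@dataclass
class SyntheticConfig:
    n_assays: int = 40
    assay_size_range: tuple[int, int] = (6, 14)  # ligands per assay, inclusive
    n_residues_range: tuple[int, int] = (12, 24)
    n_atoms_range: tuple[int, int] = (8, 16)
    lattice_spacing: float = 5.5  # A between CA positions
    lattice_jitter: float = 0.8  # A, uniform perturbation of lattice sites
    ligand_radius: float = 2.0  # A, atom blob radius around the ligand centroid
    placement_range: tuple[float, float] = (2.0, 12.0)  # centroid-pocket distance, A
    contact_cutoff: float = 12.0  # A, matches the interaction-graph cutoff
    affinity_slope: float = 0.02  # pAff per contact (alpha)
    intercept: float = 4.0  # pAff at zero contacts
    assay_offset_sd: float = 0.4  # sigma_assay: per-assay systematic offset, pAff
    type_shift: float = -0.5  # delta_type: added to pAff of IC50 assays
    noise_sd: float = 0.1  # sigma_eps: per-measurement noise, pAff
    pose_jitter: float = 0.3  # A, coordinate noise emulating docking error
    type_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # IC50, Ki, Kd
    seed: int = 0

    def __post_init__(self):
        if self.assay_size_range[0] < 2:
            raise ValueError("assays need at least two ligands")
        for name in ("assay_offset_sd", "noise_sd", "pose_jitter", "lattice_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    """Full provenance of one generated collection; regenerable from seed."""

    config: dict
    assay_offsets: dict[str, float] = field(default_factory=dict)
    assay_types: dict[str, str] = field(default_factory=dict)
    complexes: list[dict] = field(default_factory=list)  # per-complex records

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "config": self.config,
                "assay_offsets": self.assay_offsets,
                "assay_types": self.assay_types,
                "complexes": self.complexes,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def planted_affinity(
    contacts: int,
    assay_offset: float,
    type_shift: float,
    noise: float,
    cfg: SyntheticConfig,
) -> tuple[float, float]:
    """The planted affinity law; returns (pAff, value in nM)."""
    if contacts < 0:
        raise ValueError("contact count must be >= 0")
    paff = cfg.intercept + cfg.affinity_slope * contacts + assay_offset + type_shift + noise
    return paff, 10.0 ** (9.0 - paff)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _make_protein(cfg: SyntheticConfig, rng: np.random.Generator, protein_id: str):
    """Residues on a jittered cubic lattice; pocket = centroid of the CAs."""
    n_res = int(rng.integers(cfg.n_residues_range[0], cfg.n_residues_range[1] + 1))
    side = int(np.ceil(n_res ** (1.0 / 3.0)))
    sites = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n_res]
    coords = sites * cfg.lattice_spacing + rng.uniform(
        -cfg.lattice_jitter, cfg.lattice_jitter, size=(n_res, 3)
    )
    names = rng.choice(STANDARD_RESIDUES, size=n_res)
    residues = [
        ResidueRecord(index=i, residue_name=str(names[i]), ca_coord=coords[i])
        for i in range(n_res)
    ]
    pocket = coords.mean(axis=0)
    return residues, pocket


def _make_ligand(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    pocket: np.ndarray,
) -> list[AtomRecord]:
    """Atom blob placed at a random distance from the pocket center."""
    n_atoms = int(rng.integers(cfg.n_atoms_range[0], cfg.n_atoms_range[1] + 1))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    dist = rng.uniform(*cfg.placement_range)
    center = pocket + direction * dist
    coords = center + rng.uniform(-cfg.ligand_radius, cfg.ligand_radius, size=(n_atoms, 3))
    coords += rng.normal(0.0, cfg.pose_jitter, size=coords.shape)
    elements = rng.choice(LIGAND_ELEMENTS, size=n_atoms)
    return [
        AtomRecord(index=i, element=str(elements[i]), coord=coords[i])
        for i in range(n_atoms)
    ]


def make_complex(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    protein_id: str = "SYNPROT",
    ligand_id: str = "SYNLIG",
    protein: list[ResidueRecord] | None = None,
    pocket: np.ndarray | None = None,
) -> tuple[ComplexStructure, int]:
    """Generate one complex and its true contact count.

    At least one residue-atom pair within the contact cutoff is guaranteed
    (the placement is retried otherwise).  The contact count is computed
    from the emitted coordinates, so a brute-force recount over the written
    files reproduces it exactly.
    """
    if protein is None:
        protein, pocket = _make_protein(cfg, rng, protein_id)
    for _ in range(100):
        ligand = _make_ligand(cfg, rng, pocket)
        ig = build_interaction_graph(protein, ligand, cfg.contact_cutoff)
        if ig.edges:
            break
    else:  # pragma: no cover - placement range keeps contacts plentiful
        raise RuntimeError("could not place ligand within contact range")
    cs = ComplexStructure(
        protein=protein, ligand=ligand, protein_id=protein_id, ligand_id=ligand_id
    )
    return cs, len(ig.edges)


# ---------------------------------------------------------------------------
# Collections
# ---------------------------------------------------------------------------


def make_assay_collection(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[AffinityRecord], dict[tuple[str, str], ComplexStructure], SyntheticTruth]:
    """Generate a full bioassay collection.

    Returns the affinity records (satisfying all eight curation criteria by
    construction), the complex for every (assay, ligand), and the planted
    truth.  Within an assay all ligands share one protein target and one
    measurement type; sizes are >= 2.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records: list[AffinityRecord] = []
    complexes: dict[tuple[str, str], ComplexStructure] = {}
    truth = SyntheticTruth(config=asdict(cfg))
    measure_types = ("IC50", "Ki", "Kd")
    for a in range(cfg.n_assays):
        assay_id = f"ASSAY{a:04d}"
        target_id = f"T{a:04d}"
        protein, pocket = _make_protein(cfg, rng, target_id)
        mtype = str(rng.choice(measure_types, p=cfg.type_probs))
        b_assay = float(rng.normal(0.0, cfg.assay_offset_sd)) if cfg.assay_offset_sd else 0.0
        tshift = cfg.type_shift if mtype == "IC50" else 0.0
        truth.assay_offsets[assay_id] = b_assay
        truth.assay_types[assay_id] = mtype
        n_lig = int(rng.integers(cfg.assay_size_range[0], cfg.assay_size_range[1] + 1))
        for m in range(n_lig):
            ligand_id = f"L{a:04d}_{m:02d}"
            cs, contacts = make_complex(
                cfg, rng, target_id, ligand_id, protein=protein, pocket=pocket
            )
            eps = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else 0.0
            paff, nm = planted_affinity(contacts, b_assay, tshift, eps, cfg)
            records.append(
                AffinityRecord(
                    assay_id=assay_id,
                    target_id=target_id,
                    ligand_id=ligand_id,
                    value=nm,
                    measure_type=mtype,
                )
            )
            complexes[(assay_id, ligand_id)] = cs
            truth.complexes.append(
                {
                    "assay_id": assay_id,
                    "ligand_id": ligand_id,
                    "contacts": contacts,
                    "true_paff": paff,
                    "value_nM": nm,
                    "measure_type": mtype,
                }
            )
    return records, complexes, truth


# ---------------------------------------------------------------------------
# File emission (minimal standards-compliant PDB / SDF V2000)
# ---------------------------------------------------------------------------


def write_pdb(cs: ComplexStructure, path: str | Path) -> None:
    """Write the protein as CA-only ATOM records."""
    lines = []
    for r in cs.protein:
        x, y, z = r.ca_coord
        lines.append(
            f"ATOM  {r.index + 1:5d}  CA  {r.residue_name:>3s} A{r.index + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C  "
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sdf(cs: ComplexStructure, path: str | Path) -> None:
    """Write the ligand as a single-record V2000 SDF (no bond block)."""
    n = len(cs.ligand)
    lines = [
        cs.ligand_id or "LIG",
        "  assaybind synthetic",
        "",
        f"{n:3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for a in cs.ligand:
        x, y, z = a.coord
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    lines.append("M  END")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


def emit_collection(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[Path, Path, Path]:
    """Generate a collection and write assays.tsv, complexes/ and truth.json."""
    out = Path(out_dir)
    (out / "complexes").mkdir(parents=True, exist_ok=True)
    records, complexes, truth = make_assay_collection(cfg, rng)
    table = out / "assays.tsv"
    write_affinity_table(records, table)
    for (assay_id, ligand_id), cs in complexes.items():
        stem = out / "complexes" / f"{assay_id}_{ligand_id}"
        write_pdb(cs, stem.with_suffix(".pdb"))
        write_sdf(cs, stem.with_suffix(".sdf"))
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    return table, out / "complexes", truth_path
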