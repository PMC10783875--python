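"""Loading a collection directory (assays.tsv + complexes/) for training."""

from __future__ import annotations

from pathlib import Path

from .bioassay_data import apply_chembl_filters, group_into_assays, read_affinity_table
from .complex_graphs import ComplexStructure, parse_ligand, parse_protein
from .multitask_model import ModelConfig
from .training import PairStream, filter_contactable


def load_collection_dir(directory: str | Path, model_cfg: ModelConfig) -> PairStream:
    """Read a collection directory as written by ``emit_collection`` / the
    ``make-synthetic`` subcommand, curate it and return a pair stream."""
    directory = Path(directory)
    records = read_affinity_table(directory / "assays.tsv")
    survivors, report = apply_chembl_filters(records)
    assays = group_into_assays(survivors, report)
    complexes: dict[tuple[str, str], ComplexStructure] = {}
    for assay in assays:
        for ligand_id, _ in assay.records:
            stem = directory / "complexes" / f"{assay.assay_id}_{ligand_id}"
            complexes[(assay.assay_id, ligand_id)] = ComplexStructure(
                protein=parse_protein(stem.with_suffix(".pdb")),
                ligand=parse_ligand(stem.with_suffix(".sdf")),
                protein_id=assay.target_id,
                ligand_id=ligand_id,
            )
    assays, tensors, _ = filter_contactable(assays, complexes, model_cfg)
    return PairStream(assays=assays, conformations=tensors, model_cfg=model_cfg)
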