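"""Represent a protein-ligand complex as ligand/protein/interaction graphs.

Generates one synthetic complex, writes it to standard PDB + SDF files,
parses them back and builds the three distance-thresholded graphs
(cutoffs 5.0 / 8.0 / 12.0 Angstrom, strict '<').
"""

import tempfile
from pathlib import Path

import numpy as np

import assaybind as ab
from assaybind.synthetic_data import write_pdb, write_sdf

cs, contacts = ab.make_complex(ab.SyntheticConfig(), np.random.default_rng(4))

with tempfile.TemporaryDirectory() as tmp:
    write_pdb(cs, Path(tmp) / "protein.pdb")
    write_sdf(cs, Path(tmp) / "ligand.sdf")
    protein = ab.parse_protein(Path(tmp) / "protein.pdb")
    ligand = ab.parse_ligand(Path(tmp) / "ligand.sdf")

complex_ = ab.ComplexStructure(protein=protein, ligand=ligand)
lg, pg, ig = ab.build_complex_graphs(complex_)

print(f"ligand graph:      {len(lg.nodes)} atoms, {len(lg.edges)} edges (< {lg.cutoff} A)")
print(f"protein graph:     {len(pg.nodes)} residues, {len(pg.edges)} edges (< {pg.cutoff} A)")
print(f"interaction graph: {len(ig.edges)} residue-atom contacts (< {ig.cutoff} A)")
print(f"planted contact count from the generator: {contacts}")
# The interaction edge count equals the generator's planted contact count:
# the quantity the synthetic affinity is a linear function of.
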