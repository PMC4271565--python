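import numpy as np
import pytest

from nucbond.model import Atom, Chain, Residue, Structure
from nucbond.structure_io import classify_chain, read_structure


def build_structure(chain_specs, entry_id="TEST", method="X-RAY DIFFRACTION", resolution=2.0):
    """Assemble an in-memory Structure from nested plain-data specs.

    chain_specs: list of (chain_id, [(res_name, seqid, {atom_name: xyz}), ...])
    Elements are guessed from the first letter of the atom name.
    """
    structure = Structure(entry_id=entry_id, method=method, resolution=resolution)
    for chain_id, residues in chain_specs:
        chain = Chain(id=chain_id)
        for res_name, seqid, atoms in residues:
            residue = Residue(name=res_name, seqid=seqid)
            for atom_name, pos in atoms.items():
                element = atom_name[0] if atom_name[0] in "CNOPS" else "C"
                residue.atoms.append(
                    Atom(name=atom_name, element=element, position=np.asarray(pos, float))
                )
            chain.residues.append(residue)
        chain.kind = classify_chain(chain)
        structure.chains.append(chain)
    return structure


@pytest.fixture
def parse_text(tmp_path):
    """Write PDB text to a temp file and parse it through the real reader."""

    def _parse(text, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return read_structure(path)

    return _parse


# Backbone amide donor whose inferred hydrogen lands exactly at (1, 0, 0):
# the C(prev)/CA frame is mirror-symmetric about the x axis, so the bisector
# is the x axis with no floating-point residue.  Used by the boundary tests.
def amide_probe_chain():
    return (
        "A",
        [
            ("GLY", 1, {"C": [-0.766, 0.643, 0.0]}),
            ("GLY", 2, {"N": [0.0, 0.0, 0.0], "CA": [-0.766, -0.643, 0.0]}),
        ],
    )


def acceptor_chain(acc_pos, ant_pos):
    """A uracil O4/C4 fragment: single acceptor with a single antecedent."""
    return ("B", [("U", 1, {"O4": acc_pos, "C4": ant_pos})])
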