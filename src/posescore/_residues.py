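"""Amino-acid residue templates in peptide context.

Each canonical residue is written as an acetyl / N-methylamide capped SMILES
so that backbone atoms carry their in-chain valences.  The first three atoms
of every SMILES are the acetyl cap and the last two the C-terminal cap; the
``names`` list assigns PDB atom names to the residue's own atoms, in SMILES
atom order.  Side chains use the protonation states structure-preparation
pipelines assign at physiological pH; ``VARIANT_TEMPLATES`` adds the further
protonation forms such pipelines may emit (protonated histidine, neutral
arginine), which enter only the atom-type vocabulary, not per-atom naming.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem

__all__ = ["AA_TEMPLATES", "VARIANT_TEMPLATES", "template_mol", "residue_atoms"]

# resname -> (capped SMILES, atom names for the residue's atoms)
AA_TEMPLATES: dict[str, tuple[str, list[str]]] = {
    "ALA": ("CC(=O)NC(C)C(=O)NC", ["N", "CA", "CB", "C", "O"]),
    "GLY": ("CC(=O)NCC(=O)NC", ["N", "CA", "C", "O"]),
    "VAL": ("CC(=O)NC(C(C)C)C(=O)NC", ["N", "CA", "CB", "CG1", "CG2", "C", "O"]),
    "LEU": ("CC(=O)NC(CC(C)C)C(=O)NC", ["N", "CA", "CB", "CG", "CD1", "CD2", "C", "O"]),
    "ILE": ("CC(=O)NC(C(C)CC)C(=O)NC", ["N", "CA", "CB", "CG2", "CG1", "CD1", "C", "O"]),
    "PRO": ("CC(=O)N1CCCC1C(=O)NC", ["N", "CD", "CG", "CB", "CA", "C", "O"]),
    "PHE": ("CC(=O)NC(Cc1ccccc1)C(=O)NC",
            ["N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2", "C", "O"]),
    "TYR": ("CC(=O)NC(Cc1ccc(O)cc1)C(=O)NC",
            ["N", "CA", "CB", "CG", "CD1", "CE1", "CZ", "OH", "CE2", "CD2", "C", "O"]),
    "TRP": ("CC(=O)NC(Cc1c[nH]c2ccccc12)C(=O)NC",
            ["N", "CA", "CB", "CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2", "C", "O"]),
    "SER": ("CC(=O)NC(CO)C(=O)NC", ["N", "CA", "CB", "OG", "C", "O"]),
    "THR": ("CC(=O)NC(C(O)C)C(=O)NC", ["N", "CA", "CB", "OG1", "CG2", "C", "O"]),
    "CYS": ("CC(=O)NC(CS)C(=O)NC", ["N", "CA", "CB", "SG", "C", "O"]),
    "MET": ("CC(=O)NC(CCSC)C(=O)NC", ["N", "CA", "CB", "CG", "SD", "CE", "C", "O"]),
    "ASN": ("CC(=O)NC(CC(N)=O)C(=O)NC", ["N", "CA", "CB", "CG", "ND2", "OD1", "C", "O"]),
    "GLN": ("CC(=O)NC(CCC(N)=O)C(=O)NC", ["N", "CA", "CB", "CG", "CD", "NE2", "OE1", "C", "O"]),
    "ASP": ("CC(=O)NC(CC([O-])=O)C(=O)NC", ["N", "CA", "CB", "CG", "OD2", "OD1", "C", "O"]),
    "GLU": ("CC(=O)NC(CCC([O-])=O)C(=O)NC", ["N", "CA", "CB", "CG", "CD", "OE2", "OE1", "C", "O"]),
    "LYS": ("CC(=O)NC(CCCC[NH3+])C(=O)NC", ["N", "CA", "CB", "CG", "CD", "CE", "NZ", "C", "O"]),
    "ARG": ("CC(=O)NC(CCCNC(=[NH2+])N)C(=O)NC",
            ["N", "CA", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2", "C", "O"]),
    "HIS": ("CC(=O)NC(Cc1c[nH]cn1)C(=O)NC",
            ["N", "CA", "CB", "CG", "CD2", "NE2", "CE1", "ND1", "C", "O"]),
}

# additional protonation forms (vocabulary derivation only)
VARIANT_TEMPLATES: dict[str, str] = {
    "HIP": "CC(=O)NC(Cc1c[nH]c[nH+]1)C(=O)NC",   # doubly protonated His
    "ARN": "CC(=O)NC(CCCNC(=N)N)C(=O)NC",        # neutral-guanidine Arg
}

_N_CAP_FRONT = 3  # acetyl cap: atoms 0..2
_N_CAP_BACK = 2   # N-methylamide cap: last two atoms


@lru_cache(maxsize=None)
def template_mol(resname: str) -> Chem.Mol:
    smiles = AA_TEMPLATES[resname][0] if resname in AA_TEMPLATES else VARIANT_TEMPLATES[resname]
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - templates are static
        raise RuntimeError(f"bad residue template: {resname}")
    return mol


def residue_atoms(resname: str) -> list[tuple[str, Chem.Atom]]:
    """(atom name, RDKit atom) pairs for the residue's own atoms.

    Variant templates have no atom names; their atoms are returned with
    empty names (they contribute types, not per-atom lookups).
    """
    mol = template_mol(resname)
    n = mol.GetNumAtoms()
    own = range(_N_CAP_FRONT, n - _N_CAP_BACK)
    if resname in AA_TEMPLATES:
        names = AA_TEMPLATES[resname][1]
        assert len(names) == len(own)
    else:
        names = [""] * len(own)
    return [(names[k], mol.GetAtomWithIdx(i)) for k, i in enumerate(own)]
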