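"""Molecular and physicochemical descriptors.

Covers the descriptor panel feeding the bioavailability radar, the rule-based
filters, the solubility/PK models and the SVM feature matrix, plus the
1024-bit linear-path fingerprint used for synthetic-accessibility scoring and
cluster balancing.

Conventions
-----------
* TPSA is the Ertl fragmental sum with sulfur and phosphorus treated as
  polar atoms.
* Rotatable bonds are non-ring single bonds between non-terminal heavy
  atoms, excluding amide C-N (the definition behind the Veber rule).
* HBA/HBD come in two flavours: Lipinski-style (all N+O / all NH+OH) and the
  stricter pharmacophoric definitions used by the Muegge filter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Lipinski, rdMolDescriptors
from rdkit.Chem.Descriptors import MolWt

from .chemio import Molecule

N_BITS = 1024
MAX_PATH_BONDS = 7
FP_DIALECT = f"path1-{MAX_PATH_BONDS}/fnv1a32/{N_BITS}"


def _as_mol(m: Molecule | Chem.Mol) -> Chem.Mol:
    return m.mol if isinstance(m, Molecule) else m


def tpsa(m: Molecule | Chem.Mol) -> float:
    """Topological polar surface area in A^2 (polar S and P included)."""
    return rdMolDescriptors.CalcTPSA(_as_mol(m), includeSandP=True)


def fraction_csp3(m: Molecule | Chem.Mol) -> float:
    """Ratio of sp3-hybridized carbons over the total carbon count.

    Defined as 0.0 for a carbon-free molecule (flagged in the panel).
    """
    mol = _as_mol(m)
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    if n_c == 0:
        return 0.0
    return rdMolDescriptors.CalcFractionCSP3(mol)


def rotatable_bonds(m: Molecule | Chem.Mol) -> int:
    """Count of rotatable bonds (amide C-N excluded)."""
    return rdMolDescriptors.CalcNumRotatableBonds(
        _as_mol(m), rdMolDescriptors.NumRotatableBondsOptions.Strict
    )


def molar_refractivity(m: Molecule | Chem.Mol) -> float:
    """Wildman-Crippen molar refractivity (sum of per-atom contributions)."""
    return Crippen.MolMR(_as_mol(m))


def hba_lipinski(m: Molecule | Chem.Mol) -> int:
    """Lipinski H-bond acceptors: every N and O atom."""
    return Lipinski.NOCount(_as_mol(m))


def hbd_lipinski(m: Molecule | Chem.Mol) -> int:
    """Lipinski H-bond donors: every N-H and O-H."""
    return Lipinski.NHOHCount(_as_mol(m))


def hba_strict(m: Molecule | Chem.Mol) -> int:
    """Pharmacophoric H-bond acceptor count (Muegge-style)."""
    return rdMolDescriptors.CalcNumHBA(_as_mol(m))


def hbd_strict(m: Molecule | Chem.Mol) -> int:
    """Pharmacophoric H-bond donor count (Muegge-style)."""
    return rdMolDescriptors.CalcNumHBD(_as_mol(m))


# --------------------------------------------------------------------------
# 1024-bit linear-path fingerprint
# --------------------------------------------------------------------------

def _fnv1a32(data: bytes) -> int:
    h = 0x811C9DC5
    for byte in data:
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def _path_key(mol: Chem.Mol, path: list[int]) -> bytes:
    """Direction-invariant byte encoding of a linear atom path.

    Atoms are encoded as (atomic number, formal charge + 8), bonds as twice
    the bond order (aromatic = 3); the lexicographically smaller of the two
    directional encodings is the canonical key.
    """

    def encode(indices: list[int]) -> bytes:
        out = bytearray()
        for i, idx in enumerate(indices):
            a = mol.GetAtomWithIdx(idx)
            out.append(a.GetAtomicNum())
            out.append(a.GetFormalCharge() + 8)
            if i + 1 < len(indices):
                b = mol.GetBondBetweenAtoms(idx, indices[i + 1])
                out.append(int(2 * b.GetBondTypeAsDouble()))
        return bytes(out)

    fwd = encode(path)
    rev = encode(path[::-1])
    return min(fwd, rev)


def _enumerate_paths(mol: Chem.Mol, max_bonds: int = MAX_PATH_BONDS):
    """Yield every simple linear path of 1..max_bonds bonds once.

    Paths over heavy atoms only (hydrogens are implicit); each undirected
    path is emitted a single time (start index < end index).
    """
    adjacency = [
        [n.GetIdx() for n in atom.GetNeighbors()] for atom in mol.GetAtoms()
    ]

    def dfs(path: list[int], visited: set[int]):
        if len(path) >= 2 and path[0] < path[-1]:
            yield list(path)
        if len(path) == max_bonds + 1:
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in visited:
                path.append(nxt)
                visited.add(nxt)
                yield from dfs(path, visited)
                visited.remove(nxt)
                path.pop()

    for start in range(mol.GetNumAtoms()):
        yield from dfs([start], {start})


def fp2_fingerprint(m: Molecule | Chem.Mol, n_bits: int = N_BITS) -> np.ndarray:
    """Hashed linear-path fingerprint (boolean vector of length ``n_bits``).

    All simple paths of 1-7 bonds over heavy atoms are enumerated, encoded in
    a traversal-direction-invariant form and hashed (32-bit FNV-1a) onto the
    bit vector. Deterministic and invariant to atom renumbering.
    """
    mol = _as_mol(m)
    bits = np.zeros(n_bits, dtype=bool)
    for path in _enumerate_paths(mol):
        bits[_fnv1a32(_path_key(mol, path)) % n_bits] = True
    return bits


# --------------------------------------------------------------------------
# Descriptor panel
# --------------------------------------------------------------------------

_SMARTS_COUNTS = {
    "amide_groups": "[NX3][CX3](=[OX1])",
    "ester_groups": "[#6][CX3](=O)[OX2H0][#6]",
    "carboxylic_acids": "[CX3](=O)[OX2H1]",
    "hydroxyl_groups": "[OX2H]",
    "ether_oxygens": "[OD2]([#6])[#6]",
    "carbonyl_groups": "[CX3]=[OX1]",
    "nitro_groups": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "nitrile_groups": "[NX1]#[CX2]",
    "primary_amines": "[NX3;H2;!$(NC=O)]",
    "secondary_amines": "[NX3;H1;!$(NC=O)]",
    "tertiary_amines": "[NX3;H0;!$(NC=O);!$(N=*);!a]",
    "sulfonyl_groups": "[$([#16X4](=[OX1])=[OX1])]",
    "thioether_sulfurs": "[SX2]([#6])[#6]",
    "aromatic_nitrogens": "[n]",
    "aromatic_oxygens": "[o]",
    "aromatic_sulfurs": "[s]",
    "guanidine_groups": "[NX3][CX3](=[NX2])[NX3]",
    "phenol_groups": "[OX2H][c]",
    "aniline_nitrogens": "[NX3][c]",
    "halogens_on_aromatic": "[F,Cl,Br,I][c]",
}
_SMARTS_COUNTS = {k: Chem.MolFromSmarts(v) for k, v in _SMARTS_COUNTS.items()}


@dataclass
class DescriptorSet:
    """The per-molecule descriptor panel.

    The named attributes are the descriptors with model roles; ``extras``
    carries additional atom-type / group counts so the full panel (about 50
    features) is available to the SVM pipeline via :meth:`panel`.
    """

    mw: float
    heavy_atoms: int
    aromatic_heavy_atoms: int
    fraction_csp3: float
    rotatable_bonds: int
    hba: int
    hbd: int
    hba_strict: int
    hbd_strict: int
    mr: float
    tpsa: float
    formal_charge: int
    ring_count: int
    aromatic_ring_count: int
    heteroatoms: int
    carbon_count: int
    total_atoms: int
    stereo_centers: int
    spiro_atoms: int
    bridgehead_atoms: int
    macrocycle_count: int
    carbon_free: bool
    extras: dict[str, float]

    def panel(self) -> dict[str, float]:
        """Flat name -> value mapping of the full descriptor panel."""
        out = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name not in ("extras", "carbon_free")
        }
        out.update(self.extras)
        return out


def compute_descriptor_panel(m: Molecule | Chem.Mol) -> DescriptorSet:
    """Compute the full descriptor panel for a standardized molecule."""
    mol = _as_mol(m)
    ring_info = mol.GetRingInfo()
    n_c = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    extras: dict[str, float] = {
        "nitrogen_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7),
        "oxygen_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8),
        "sulfur_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 16),
        "phosphorus_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 15),
        "fluorine_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 9),
        "chlorine_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 17),
        "bromine_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 35),
        "iodine_count": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 53),
        "sp3_carbons": sum(
            1
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.GetHybridization() == Chem.HybridizationType.SP3
        ),
        "sp2_carbons": sum(
            1
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6
            and a.GetHybridization() == Chem.HybridizationType.SP2
        ),
        "positive_atoms": sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() > 0),
        "negative_atoms": sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() < 0),
        "hydrogen_count": sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        "saturated_ring_count": rdMolDescriptors.CalcNumSaturatedRings(mol),
        "aliphatic_ring_count": rdMolDescriptors.CalcNumAliphaticRings(mol),
        "max_ring_size": max((len(r) for r in ring_info.AtomRings()), default=0),
        "fused_ring_bonds": sum(
            1 for b in mol.GetBonds() if ring_info.NumBondRings(b.GetIdx()) > 1
        ),
        "double_bonds": sum(
            1
            for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
        ),
        "triple_bonds": sum(
            1
            for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.TRIPLE
        ),
    }
    for key, patt in _SMARTS_COUNTS.items():
        extras[key] = len(mol.GetSubstructMatches(patt))

    return DescriptorSet(
        mw=MolWt(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        aromatic_heavy_atoms=sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        fraction_csp3=fraction_csp3(mol),
        rotatable_bonds=rotatable_bonds(mol),
        hba=hba_lipinski(mol),
        hbd=hbd_lipinski(mol),
        hba_strict=hba_strict(mol),
        hbd_strict=hbd_strict(mol),
        mr=molar_refractivity(mol),
        tpsa=tpsa(mol),
        formal_charge=sum(a.GetFormalCharge() for a in mol.GetAtoms()),
        ring_count=rdMolDescriptors.CalcNumRings(mol),
        aromatic_ring_count=rdMolDescriptors.CalcNumAromaticRings(mol),
        heteroatoms=mol.GetNumHeavyAtoms() - n_c,
        carbon_count=n_c,
        total_atoms=mol.GetNumAtoms() + sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        stereo_centers=len(
            Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
        ),
        spiro_atoms=rdMolDescriptors.CalcNumSpiroAtoms(mol),
        bridgehead_atoms=rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        macrocycle_count=sum(1 for r in ring_info.AtomRings() if len(r) > 8),
        carbon_free=(n_c == 0),
        extras=extras,
    )
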