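"""Molecule input parsing, standardization and report writing.

Input lists follow the one-molecule-per-line convention: a SMILES string
optionally followed by a space and a name. Standardization keeps the largest
covalent fragment, records the as-input formal net charge, neutralizes simple
protonation states (carboxylate -> acid, ammonium -> amine), and kekulizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class InvalidSmiles(ValueError):
    """The SMILES string could not be parsed."""


class SanitizationError(ValueError):
    """The structure is chemically impossible (e.g. bad valence)."""


@dataclass(frozen=True)
class MoleculeInput:
    """One line of user input: a SMILES and an identifier."""

    smiles: str
    name: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not self.name:
            raise ValueError("name must be non-empty")


@dataclass
class Molecule:
    """A standardized structure plus bookkeeping from standardization.

    Attributes
    ----------
    mol : rdkit.Chem.Mol
        Sanitized, neutralized molecule in aromatic perception form.
    kekulized : rdkit.Chem.Mol
        Same structure with aromatic bonds resolved to alternating orders.
    name : str
        Identifier carried from the input.
    input_smiles : str
        The SMILES as supplied.
    input_net_charge : int
        Formal net charge of the kept fragment *before* neutralization;
        charge-dependent scores use this value.
    neutralized : bool
        True if any protonation state was changed.
    fragment_stripped : bool
        True if counter-ions / minor fragments were removed.
    """

    mol: Chem.Mol
    kekulized: Chem.Mol
    name: str
    input_smiles: str
    input_net_charge: int
    neutralized: bool = False
    fragment_stripped: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.mol.GetAtoms())

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


def parse_input_list(text: str) -> list[MoleculeInput]:
    """Parse a multiline SMILES list into :class:`MoleculeInput` records.

    One molecule per non-blank line; the token after the first space is the
    name (anything beyond it is ignored). Unnamed molecules get
    ``Molecule_<k>`` with k the 1-based position among non-blank lines.
    Syntactic SMILES errors are *not* raised here; they surface at
    :func:`standardize`.
    """
    out: list[MoleculeInput] = []
    k = 0
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        k += 1
        tokens = line.split()
        smiles = tokens[0]
        name = tokens[1] if len(tokens) > 1 else f"Molecule_{k}"
        out.append(MoleculeInput(smiles=smiles, name=name))
    return out


# Atoms carrying a +/- charge that can be fixed by moving a proton, and that
# are not part of a charge-separated group (e.g. nitro, N-oxide) whose
# counter-charge sits on a neighbour.
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Convert simple protonation states to the neutral form in place.

    O(-)/S(-)/N(-) gain a proton; protonated amines lose one. Quaternary
    ammonium and other permanent charges are untouched, as are
    charge-separated functional groups.
    """
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return mol, False
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h - charge))
        atom.UpdatePropertyCache()
    mol = mol.GetMol()
    Chem.SanitizeMol(mol)
    return mol, True


def standardize(inp: MoleculeInput | str, name: str | None = None) -> Molecule:
    """Parse and standardize one input molecule.

    Steps: parse; sanitize; keep the largest covalent fragment; record the
    as-input net charge; neutralize simple protonation states; kekulize.

    Raises
    ------
    InvalidSmiles
        If the SMILES does not parse.
    SanitizationError
        If the structure fails valence/aromaticity checks.
    """
    if isinstance(inp, str):
        inp = MoleculeInput(smiles=inp, name=name or "Molecule_1")
    mol = Chem.MolFromSmiles(inp.smiles, sanitize=False)
    if mol is None or mol.GetNumAtoms() == 0:
        raise InvalidSmiles(f"unparseable SMILES: {inp.smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types
        raise SanitizationError(f"{inp.smiles!r}: {exc}") from exc

    warnings: list[str] = []
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    stripped = False
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), f.GetNumAtoms()))
        stripped = True
        warnings.append("minor fragments / counter-ions removed")

    input_net_charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    mol, neutralized = _neutralize(mol)
    if neutralized:
        warnings.append("protonation state neutralized")

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    return Molecule(
        mol=mol,
        kekulized=kek,
        name=inp.name,
        input_smiles=inp.smiles,
        input_net_charge=input_net_charge,
        neutralized=neutralized,
        fragment_stripped=stripped,
        warnings=warnings,
    )


def canonical_smiles(m: Molecule | Chem.Mol) -> str:
    """Canonical SMILES of the standardized (neutralized, aromatic) form."""
    mol = m.mol if isinstance(m, Molecule) else m
    return Chem.MolToSmiles(mol)


def write_report(frame, path) -> None:
    """Write a tabular report (one row per molecule) as CSV.

    ``frame`` is a pandas DataFrame as produced by
    :meth:`admeprofiler.profile.ADMEProfiler.transform`; the column order is
    preserved so the schema is stable across runs.
    """
    frame.to_csv(path, index=False)
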