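"""Octanol/water partition coefficient (log P) predictors and consensus.

Three predictors are computed natively:

* ``wlogp`` — the Wildman-Crippen purely atomistic contribution system.
* ``mlogp`` — the Moriguchi topological regression on 13 structural
  parameters.
* ``fragment_logp`` — a table-driven hybrid model (SMARTS-keyed fragment
  coefficients plus topological-descriptor terms). The packaged default
  table is a synthetic stand-in; users supply their own coefficients for a
  specific fragmental system.

Predictors that need external physics or closed-source software (e.g. a
solvation-free-energy method, XLOGP3) enter as *external value slots*: a
mapping predictor-name -> value read from a user-supplied file. The
consensus log P is the arithmetic mean of every available value.

Downstream models that call for an XLOGP3-style lipophilicity use a
pluggable slot defaulting to ``wlogp`` when no external value is present
(the substitution is flagged in reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Crippen

from .chemio import Molecule
from .descriptors import _as_mol


class MissingTable(ValueError):
    """No fragment coefficient table is available."""


class NoPredictorAvailable(ValueError):
    """Consensus requested with zero available predictor values."""


def wlogp(m: Molecule | Chem.Mol) -> float:
    """Wildman-Crippen atomistic log P (sum of per-atom contributions)."""
    return Crippen.MolLogP(_as_mol(m))


# --------------------------------------------------------------------------
# Moriguchi MLOGP
# --------------------------------------------------------------------------

# Regression weights of the published 13-parameter model; the final entry is
# the intercept.
_MLOGP_COEF = {
    "CX": 1.244,    # (carbons + weighted halogens) ** 0.6
    "NO": -1.017,   # (N + O count) ** 0.9
    "PRX": 0.406,   # N/O proximity pairs
    "UB": -0.145,   # (unsaturated bonds excl. nitro) ** 0.8
    "HB": 0.511,    # intramolecular H-bond dummy
    "POL": 0.268,   # aromatic polar substituents
    "AMP": -2.215,  # amphoteric character
    "ALK": 0.912,   # alkane/alkene dummy
    "RNG": -0.392,  # non-carboaromatic ring dummy
    "QN": -3.684,   # quaternary N (1.0) / N-oxide (0.5)
    "NO2": 0.474,   # nitro group count
    "NCS": 1.582,   # isothiocyanate (1.0) / thiocyanate (0.5)
    "BLM": 0.773,   # beta-lactam dummy
}
MLOGP_INTERCEPT = -1.041

_HALOGEN_WEIGHT = {9: 0.5, 17: 1.0, 35: 1.5, 53: 2.0}

_PAT_NITRO = Chem.MolFromSmarts("[$([NX3](=O)=O),$([NX3+](=O)[O-])]")
_PAT_QUAT_N = Chem.MolFromSmarts("[NX4+,NX4]")
_PAT_N_OXIDE = Chem.MolFromSmarts("[NX3+]-[OX1-]")
_PAT_NCS = Chem.MolFromSmarts("N=C=S")
_PAT_SCN = Chem.MolFromSmarts("S-C#N")
_PAT_BETA_LACTAM = Chem.MolFromSmarts("[NX3]1[CX3](=O)[CX4][CX4]1")
_PAT_ALPHA_AMINO_ACID = Chem.MolFromSmarts(
    "[NX3;H2,H1;!$(NC=O)][CX4][CX3](=O)[OX2H1,OX1-]"
)
_PAT_AMINOBENZOIC = Chem.MolFromSmarts("[NX3;H2,H1]c1ccccc1")
_PAT_ARYL_ACID = Chem.MolFromSmarts("[cX3][CX3](=O)[OX2H1,OX1-]")
_PAT_PYRIDINE_ACID = Chem.MolFromSmarts("c1ccncc1")
_PAT_DONOR = Chem.MolFromSmarts("[OX2H,NX3;!$([NX3](=O)=O)]")
_PAT_ACCEPTOR = Chem.MolFromSmarts("[OX1,OX2,nX2,NX2,NX1]")


def moriguchi_parameters(m: Molecule | Chem.Mol) -> dict[str, float]:
    """The 13 structural parameters of the Moriguchi log P regression.

    The parameters are topological counts and indicator variables; see the
    methods note for the exact operational definitions adopted where the
    original descriptions are narrative (HB, POL, AMP).
    """
    mol = _as_mol(m)
    p: dict[str, float] = {}

    p["CX"] = sum(
        1.0 if a.GetAtomicNum() == 6 else _HALOGEN_WEIGHT.get(a.GetAtomicNum(), 0.0)
        for a in mol.GetAtoms()
    )
    n_no = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    p["NO"] = float(n_no)

    # Proximity of N/O heteroatoms: +2 per directly bonded pair, +1 per pair
    # two bonds apart.
    het = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    prx = 0.0
    if len(het) > 1:
        dm = Chem.GetDistanceMatrix(mol)
        for i, a in enumerate(het):
            for b in het[i + 1:]:
                d = dm[a][b]
                if d == 1:
                    prx += 2.0
                elif d == 2:
                    prx += 1.0
    p["PRX"] = prx

    n_nitro = len(mol.GetSubstructMatches(_PAT_NITRO))
    unsat = sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
        or b.GetIsAromatic()
    )
    # aromatic rings: count each aromatic bond once; subtract the two N=O of
    # each nitro written in the charge-separated form (one double bond each).
    p["UB"] = float(max(0, unsat - n_nitro))

    # Intramolecular H-bond: donor and acceptor heteroatoms 4 bonds apart
    # with an aromatic atom on the connecting path (ortho-type chelation).
    hb = 0.0
    donors = {i for (i,) in mol.GetSubstructMatches(_PAT_DONOR)}
    acceptors = {i for (i,) in mol.GetSubstructMatches(_PAT_ACCEPTOR)}
    if donors and acceptors:
        dm = Chem.GetDistanceMatrix(mol)
        for d_idx in donors:
            for a_idx in acceptors:
                if d_idx == a_idx or dm[d_idx][a_idx] != 4:
                    continue
                path = Chem.GetShortestPath(mol, int(d_idx), int(a_idx))
                if any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in path[1:-1]):
                    hb = 1.0
                    break
            if hb:
                break
    p["HB"] = hb

    # Polar substituents on aromatic rings: count aromatic-carbon attachment
    # points whose substituent starts with a heteroatom/halogen or a carbonyl
    # carbon.
    pol = 0
    for atom in mol.GetAtoms():
        if not (atom.GetIsAromatic() and atom.GetAtomicNum() == 6):
            continue
        for nb in atom.GetNeighbors():
            if nb.GetIsAromatic():
                continue
            z = nb.GetAtomicNum()
            if z in (7, 8, 16, 9, 17, 35, 53, 15):
                pol += 1
            elif z == 6 and any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(nb).GetAtomicNum() in (7, 8, 16)
                for b in nb.GetBonds()
            ):
                pol += 1
    p["POL"] = float(pol)

    amp = 0.0
    if mol.HasSubstructMatch(_PAT_ALPHA_AMINO_ACID):
        amp = 1.0
    elif mol.HasSubstructMatch(_PAT_ARYL_ACID) and (
        mol.HasSubstructMatch(_PAT_AMINOBENZOIC)
        or mol.HasSubstructMatch(_PAT_PYRIDINE_ACID)
    ):
        amp = 0.5
    p["AMP"] = amp

    only_ch = all(a.GetAtomicNum() in (1, 6) for a in mol.GetAtoms())
    n_double = sum(
        1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
    )
    n_triple = sum(
        1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE
    )
    aromatic = any(a.GetIsAromatic() for a in mol.GetAtoms())
    p["ALK"] = 1.0 if (only_ch and not aromatic and n_triple == 0 and n_double <= 1) else 0.0

    ring_info = mol.GetRingInfo()
    rng = 0.0
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        carboaromatic = all(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms)
        if not carboaromatic:
            rng = 1.0
            break
    p["RNG"] = rng

    qn = 0.0
    if mol.HasSubstructMatch(_PAT_N_OXIDE):
        qn = 0.5
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 7 and atom.GetDegree() + atom.GetTotalNumHs() == 4:
            qn = max(qn, 1.0)
    p["QN"] = qn

    p["NO2"] = float(n_nitro)
    p["NCS"] = float(
        len(mol.GetSubstructMatches(_PAT_NCS)) * 1.0
        + len(mol.GetSubstructMatches(_PAT_SCN)) * 0.5
    )
    p["BLM"] = 1.0 if mol.HasSubstructMatch(_PAT_BETA_LACTAM) else 0.0
    return p


def mlogp_from_parameters(params: dict[str, float]) -> float:
    """Evaluate the Moriguchi regression on a parameter dict.

    With every parameter zero the value is the regression intercept.
    """
    value = MLOGP_INTERCEPT
    value += _MLOGP_COEF["CX"] * params.get("CX", 0.0) ** 0.6
    value += _MLOGP_COEF["NO"] * params.get("NO", 0.0) ** 0.9
    value += _MLOGP_COEF["UB"] * params.get("UB", 0.0) ** 0.8
    for key in ("PRX", "HB", "POL", "AMP", "ALK", "RNG", "QN", "NO2", "NCS", "BLM"):
        value += _MLOGP_COEF[key] * params.get(key, 0.0)
    return value


def mlogp(m: Molecule | Chem.Mol) -> float:
    """Moriguchi topological log P."""
    return mlogp_from_parameters(moriguchi_parameters(m))


# --------------------------------------------------------------------------
# Table-driven fragmental log P
# --------------------------------------------------------------------------

@dataclass
class FragmentTable:
    """SMARTS-keyed fragment coefficients plus descriptor-term coefficients.

    File format (tab-separated, ``#`` comments)::

        intercept\t<value>
        fragment\t<SMARTS>\t<coefficient>\t<description>
        descriptor\t<panel-descriptor-name>\t<coefficient>
    """

    intercept: float = 0.0
    fragments: list[tuple[str, float, str]] = field(default_factory=list)
    descriptors: list[tuple[str, float]] = field(default_factory=list)
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = []
        for smarts, coef, _desc in self.fragments:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS in fragment table: {smarts!r}")
            self._compiled.append((patt, coef))

    @classmethod
    def from_file(cls, path) -> "FragmentTable":
        intercept = 0.0
        fragments: list[tuple[str, float, str]] = []
        descriptors: list[tuple[str, float]] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            # '#' only comments out whole lines: SMARTS may contain '#'
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            kind = parts[0]
            if kind == "intercept":
                intercept = float(parts[1])
            elif kind == "fragment":
                desc = parts[3] if len(parts) > 3 else ""
                fragments.append((parts[1], float(parts[2]), desc))
            elif kind == "descriptor":
                descriptors.append((parts[1], float(parts[2])))
            else:
                raise ValueError(f"unknown record kind {kind!r} in {path}")
        return cls(intercept=intercept, fragments=fragments, descriptors=descriptors)


def fragment_logp(
    m: Molecule | Chem.Mol,
    table: FragmentTable | None,
    panel: dict[str, float] | None = None,
) -> float:
    """Hybrid fragmental log P: fragment-match counts + descriptor terms."""
    if table is None:
        raise MissingTable("no fragment log P coefficient table supplied")
    mol = _as_mol(m)
    value = table.intercept
    for patt, coef in table._compiled:
        value += coef * len(mol.GetSubstructMatches(patt))
    if table.descriptors:
        if panel is None:
            from .descriptors import compute_descriptor_panel

            panel = compute_descriptor_panel(mol).panel()
        for name, coef in table.descriptors:
            value += coef * panel[name]
    return value


# --------------------------------------------------------------------------
# Consensus
# --------------------------------------------------------------------------

@dataclass
class LipophilicityProfile:
    """All log P predictions for one molecule plus their consensus."""

    wlogp: float
    mlogp: float
    fragment_logp: float | None = None
    external: dict[str, float] = field(default_factory=dict)

    def available(self) -> dict[str, float]:
        out = {"WLOGP": self.wlogp, "MLOGP": self.mlogp}
        if self.fragment_logp is not None:
            out["FLOGP"] = self.fragment_logp
        out.update(self.external)
        return {k: v for k, v in out.items() if v is not None and math.isfinite(v)}

    @property
    def consensus(self) -> float:
        return consensus_logp(self)

    @property
    def n_contributors(self) -> int:
        return len(self.available())

    def lipo_slot(self, prefer: str = "XLOGP3") -> tuple[float, str]:
        """The pluggable XLOGP3-style lipophilicity value.

        Returns the externally supplied value for ``prefer`` when present,
        otherwise falls back to WLOGP; the second element names the source so
        reports can flag the substitution.
        """
        if prefer in self.external:
            return self.external[prefer], prefer
        return self.wlogp, "WLOGP"


def consensus_logp(profile: LipophilicityProfile) -> float:
    """Arithmetic mean over every available log P predictor."""
    values = list(profile.available().values())
    if not values:
        raise NoPredictorAvailable("no log P predictor value available")
    return sum(values) / len(values)


def lipophilicity_profile(
    m: Molecule | Chem.Mol,
    table: FragmentTable | None = None,
    external: dict[str, float] | None = None,
) -> LipophilicityProfile:
    """Compute all native predictors and assemble the profile."""
    try:
        flogp = fragment_logp(m, table) if table is not None else None
    except MissingTable:
        flogp = None
    return LipophilicityProfile(
        wlogp=wlogp(m),
        mlogp=mlogp(m),
        fragment_logp=flogp,
        external=dict(external or {}),
    )
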