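"""Medicinal-chemistry screens and the synthetic-accessibility (SA) score.

Structural-alert screening uses two catalogs: the PAINS promiscuous-fragment
patterns and the Brenk list of putatively toxic / reactive / unstable
groups. Catalogs can be loaded from a SMARTS file or from RDKit's curated
built-in collections (the default; the built-in PAINS set has 480 entries,
the Brenk set 105).

The SA score rests on the assumption that molecular fragments frequent in
readily purchasable compounds are easy to make. A library of molecules is
fingerprinted with the package's 1024-bit path fingerprint; each bit's
occupancy count, normalized by the maximum count, gives a per-bit
contribution ln(normalized count) (the most common fragment contributes 0,
rarer ones are negative). A molecule's mean bit contribution is combined
with size and complexity penalties (chiral centres, spiro atoms, bridged
rings, macrocycles) and mapped affinely onto [1, 10]: 1 = very easy,
10 = very difficult to synthesize.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import Molecule
from .descriptors import FP_DIALECT, N_BITS, _as_mol, fp2_fingerprint
from . import config
from .druglikeness import FilterResult
from .descriptors import DescriptorSet

EXPECTED_COUNTS = {"PAINS": 481, "BRENK": 105}


class BadPattern(ValueError):
    """A SMARTS entry in a catalog file does not compile."""


class CountMismatch(ValueError):
    """Catalog entry count differs from the expected count."""


class EmptyLibrary(ValueError):
    """Frequency-table construction over an empty molecule stream."""


class DialectMismatch(ValueError):
    """Frequency table built with a different fingerprint dialect."""


@dataclass
class SmartsCatalog:
    """A named collection of compiled SMARTS patterns with descriptions."""

    name: str
    entries: list[tuple[str, str]]  # (smarts, description)
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = []
        for i, (smarts, _desc) in enumerate(self.entries):
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise BadPattern(
                    f"catalog {self.name!r} entry {i + 1}: invalid SMARTS {smarts!r}"
                )
            self._compiled.append(patt)

    def __len__(self) -> int:
        return len(self.entries)


def load_catalog(path, expected_count: int | None = None, name: str | None = None) -> SmartsCatalog:
    """Load a catalog from a text file: ``SMARTS<TAB>description`` per line.

    Raises :class:`BadPattern` naming the offending line, and
    :class:`CountMismatch` if ``expected_count`` is given and differs.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smarts = parts[0].strip()
        desc = parts[1].strip() if len(parts) > 1 else ""
        if Chem.MolFromSmarts(smarts) is None:
            raise BadPattern(f"{path}:{lineno}: invalid SMARTS {smarts!r}")
        entries.append((smarts, desc))
    cat = SmartsCatalog(name=name or path.stem, entries=entries)
    if expected_count is not None and len(cat) != expected_count:
        raise CountMismatch(
            f"catalog {cat.name!r}: {len(cat)} entries, expected {expected_count}"
        )
    return cat


def builtin_catalog(name: str) -> SmartsCatalog:
    """RDKit's curated PAINS (480 entries) or Brenk (105 entries) catalog."""
    from rdkit.Chem import FilterCatalog
    from rdkit.Chem.FilterCatalog import FilterCatalogParams

    key = name.upper()
    params = FilterCatalogParams()
    if key == "PAINS":
        for sub in ("PAINS_A", "PAINS_B", "PAINS_C"):
            params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, sub))
    elif key == "BRENK":
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.BRENK)
    else:
        raise ValueError(f"unknown built-in catalog {name!r}")
    fc = FilterCatalog.FilterCatalog(params)
    # Patterns are pre-compiled inside the FilterCatalog; entries carry the
    # descriptions and matching is delegated to the catalog object.
    cat = SmartsCatalog.__new__(SmartsCatalog)
    cat.name = key
    cat.entries = [
        ("", fc.GetEntryWithIdx(i).GetDescription()) for i in range(fc.GetNumEntries())
    ]
    cat._compiled = None
    cat._filter_catalog = fc
    return cat


@dataclass(frozen=True)
class AlertHit:
    """One structural-alert match."""

    catalog: str
    description: str
    atoms: tuple[int, ...]


def screen(m: Molecule | Chem.Mol, cat: SmartsCatalog) -> list[AlertHit]:
    """All substructure matches of a catalog, one hit per matched pattern.

    Deterministic order (catalog order); invariant to atom renumbering up to
    the reported atom indices.
    """
    mol = _as_mol(m)
    hits: list[AlertHit] = []
    fc = getattr(cat, "_filter_catalog", None)
    if fc is not None:
        for entry in fc.GetMatches(mol):
            atoms: tuple[int, ...] = ()
            for fm in entry.GetFilterMatches(mol):
                atoms = tuple(sorted(j for _, j in fm.atomPairs))
                break
            hits.append(AlertHit(cat.name, entry.GetDescription(), atoms))
        hits.sort(key=lambda h: h.description)
        return hits
    for patt, (smarts, desc) in zip(cat._compiled, cat.entries):
        match = mol.GetSubstructMatch(patt)
        if match:
            hits.append(AlertHit(cat.name, desc or smarts, tuple(sorted(match))))
    return hits


def leadlikeness(d: DescriptorSet, logp: float, thresholds: dict | None = None) -> FilterResult:
    """Leadlikeness window: MW 250-350, lipophilicity <= 3.5, <= 7 rotatable bonds."""
    t = thresholds or config.filter_thresholds("leadlikeness")
    v = []
    if not t["mw_min"] <= d.mw <= t["mw_max"]:
        v.append(f"MW {d.mw:.2f} outside [{t['mw_min']:g}, {t['mw_max']:g}]")
    if logp > t["logp_max"]:
        v.append(f"XLOGP {logp:.2f} > {t['logp_max']:g}")
    if d.rotatable_bonds > t["rotatable_bonds_max"]:
        v.append(f"rotatable bonds {d.rotatable_bonds} > {t['rotatable_bonds_max']}")
    return FilterResult("Leadlikeness", not v, v)


# --------------------------------------------------------------------------
# Fragment-frequency table and SA score
# --------------------------------------------------------------------------

# Ertl-Schuffenhauer complexity penalty form: log10 penalties on chiral /
# spiro / bridgehead counts, a fixed macrocycle penalty, and a size term
# superlinear in the heavy-atom count.
_SIZE_EXPONENT = 1.005


@dataclass
class FragmentFrequencyTable:
    """Per-bit ln-normalized occupancy contributions over a library.

    ``contributions[b] = ln(count_b / max_count)`` for observed bits; bits
    never seen in the library carry the floor ``ln(pseudo / max_count)``
    (default pseudo-count 0.5). ``raw_min``/``raw_max`` are the calibration
    constants of the affine raw -> [1, 10] mapping, taken from the raw-score
    range of the build library.
    """

    contributions: np.ndarray
    library_size: int
    max_count: int
    dialect: str = FP_DIALECT
    pseudo_count: float = 0.5
    raw_min: float = 0.0
    raw_max: float = 0.0

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dialect": self.dialect,
                    "library_size": self.library_size,
                    "max_count": self.max_count,
                    "pseudo_count": self.pseudo_count,
                    "raw_min": self.raw_min,
                    "raw_max": self.raw_max,
                    "contributions": [round(float(c), 6) for c in self.contributions],
                }
            )
        )

    @classmethod
    def load(cls, path) -> "FragmentFrequencyTable":
        obj = json.loads(Path(path).read_text())
        return cls(
            contributions=np.asarray(obj["contributions"], dtype=float),
            library_size=int(obj["library_size"]),
            max_count=int(obj["max_count"]),
            dialect=obj["dialect"],
            pseudo_count=float(obj["pseudo_count"]),
            raw_min=float(obj["raw_min"]),
            raw_max=float(obj["raw_max"]),
        )


def bit_counts(mols) -> tuple[np.ndarray, int]:
    """Per-bit occupancy counts (number of molecules setting each bit)."""
    counts = np.zeros(N_BITS, dtype=np.int64)
    n = 0
    for mol in mols:
        counts += fp2_fingerprint(mol).astype(np.int64)
        n += 1
    return counts, n


def build_frequency_table(
    library, pseudo_count: float = 0.5, calibrate: bool = True
) -> FragmentFrequencyTable:
    """Build the fragment-frequency table from a stream of molecules.

    ``library`` yields SMILES strings, RDKit molecules or standardized
    :class:`~admeprofiler.chemio.Molecule` objects. Order-invariant.
    """
    mols = []
    for item in library:
        if isinstance(item, str):
            mol = Chem.MolFromSmiles(item)
            if mol is None:
                continue
            mols.append(mol)
        else:
            mols.append(_as_mol(item))
    if not mols:
        raise EmptyLibrary("no parseable molecule in the library stream")
    counts, n = bit_counts(mols)
    max_count = int(counts.max())
    if max_count == 0:
        raise EmptyLibrary("library molecules set no fingerprint bits")
    contributions = np.full(N_BITS, math.log(pseudo_count / max_count))
    observed = counts > 0
    contributions[observed] = np.log(counts[observed] / max_count)
    table = FragmentFrequencyTable(
        contributions=contributions,
        library_size=n,
        max_count=max_count,
        pseudo_count=pseudo_count,
    )
    if calibrate:
        raws = [sa_raw(mol, table, check_dialect=False) for mol in mols]
        lo, hi = min(raws), max(raws)
        if hi - lo < 1e-9:
            # degenerate library: anchor its members at the easy extreme
            lo = hi - 1.0
            table.raw_min, table.raw_max = lo, hi
        else:
            # widen slightly so library members do not all clip at the extremes
            span = hi - lo
            table.raw_min = lo - 0.05 * span
            table.raw_max = hi + 0.05 * span
    return table


@dataclass
class SAScore:
    """Synthetic-accessibility estimate with its penalty breakdown."""

    raw: float
    normalized: float
    fragment_term: float
    size_penalty: float
    chiral_penalty: float
    spiro_penalty: float
    bridge_penalty: float
    macrocycle_penalty: float


def sa_raw(
    m: Molecule | Chem.Mol,
    table: FragmentFrequencyTable,
    check_dialect: bool = True,
) -> float:
    """Raw SA value: mean bit contribution minus complexity/size penalties."""
    if check_dialect and table.dialect != FP_DIALECT:
        raise DialectMismatch(
            f"table dialect {table.dialect!r} != fingerprint dialect {FP_DIALECT!r}"
        )
    return _sa_components(m, table)[0]


def _sa_components(m, table):
    mol = _as_mol(m)
    bits = np.flatnonzero(fp2_fingerprint(mol))
    fragment_term = float(table.contributions[bits].mean()) if bits.size else 0.0

    n_heavy = mol.GetNumHeavyAtoms()
    size_penalty = n_heavy ** _SIZE_EXPONENT - n_heavy
    n_chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )
    from rdkit.Chem import rdMolDescriptors

    chiral_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(rdMolDescriptors.CalcNumSpiroAtoms(mol) + 1)
    bridge_penalty = math.log10(rdMolDescriptors.CalcNumBridgeheadAtoms(mol) + 1)
    macro = any(len(r) > 8 for r in mol.GetRingInfo().AtomRings())
    macrocycle_penalty = math.log10(2) if macro else 0.0

    raw = (
        fragment_term
        - size_penalty
        - chiral_penalty
        - spiro_penalty
        - bridge_penalty
        - macrocycle_penalty
    )
    return raw, (
        fragment_term,
        size_penalty,
        chiral_penalty,
        spiro_penalty,
        bridge_penalty,
        macrocycle_penalty,
    )


def normalize_sa(raw: float, table: FragmentFrequencyTable) -> float:
    """Affine raw -> [1, 10] mapping with clipping (1 easy, 10 difficult)."""
    span = table.raw_max - table.raw_min
    if span <= 0:
        return 1.0
    score = 1.0 + 9.0 * (table.raw_max - raw) / span
    return min(10.0, max(1.0, score))


def sa_score(m: Molecule | Chem.Mol, table: FragmentFrequencyTable) -> SAScore:
    """Synthetic-accessibility score of a molecule against a frequency table."""
    if table.dialect != FP_DIALECT:
        raise DialectMismatch(
            f"table dialect {table.dialect!r} != fingerprint dialect {FP_DIALECT!r}"
        )
    raw, comps = _sa_components(m, table)
    return SAScore(
        raw=raw,
        normalized=normalize_sa(raw, table),
        fragment_term=comps[0],
        size_penalty=comps[1],
        chiral_penalty=comps[2],
        spiro_penalty=comps[3],
        bridge_penalty=comps[4],
        macrocycle_penalty=comps[5],
    )


def default_sa_table() -> FragmentFrequencyTable:
    """Frequency table built over the packaged mini-library of drug-like SMILES."""
    lib = config.data_path("mini_library.smi").read_text().splitlines()
    smiles = [ln.split()[0] for ln in lib if ln.strip() and not ln.startswith("#")]
    return build_frequency_table(smiles)


def benchmark_statistics(predicted, reference) -> dict[str, float]:
    """MAE, RMSE and linear correlation r between score lists.

    Harness for user-supplied molecule / expert-score benchmark pairs.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predicted and reference must be equal-length, non-empty")
    err = p - r
    corr = float(np.corrcoef(p, r)[0, 1]) if p.size > 1 else float("nan")
    return {
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "r": corr,
    }
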