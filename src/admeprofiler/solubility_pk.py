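"""Water solubility, skin permeation and the BOILED-Egg readout.

Solubility (log10 of molar aqueous solubility, log S) is predicted by three
models:

* ESOL — Delaney's linear QSPR on log P, MW, rotatable bonds and the
  aromatic proportion of heavy atoms.
* Ali — linear in log P and TPSA (the TPSA-based model of Ali et al.).
* Fragmental — a 16-fragment contribution system modulated by sqrt(MW)
  (table-driven; the packaged default table is a synthetic stand-in).

All models take the lipophilicity value through a pluggable slot (an
XLOGP3-style external value when supplied, otherwise WLOGP).

Skin permeation uses the Potts-Guy QSPR; the coefficient is reported as
log Kp with Kp in cm/s.

The BOILED-Egg classifies passive gastrointestinal absorption (white) and
blood-brain-barrier permeation (yolk) from the position of the molecule in
the (TPSA, WLOGP) plane; the two ellipses are loaded from a config file and
are not mutually exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem

from .chemio import Molecule
from .descriptors import DescriptorSet, _as_mol
from .lipophilicity import FragmentTable, MissingTable

# Solubility class scale on log S:
# insoluble < -10 < poorly < -6 < moderately < -4 < soluble < -2 < very < 0 < highly
SOLUBILITY_CLASS_BOUNDS = [-10.0, -6.0, -4.0, -2.0, 0.0]
SOLUBILITY_CLASS_LABELS = [
    "insoluble",
    "poorly soluble",
    "moderately soluble",
    "soluble",
    "very soluble",
    "highly soluble",
]

# ESOL (Delaney) coefficients: intercept, logP, MW, rotatable bonds,
# aromatic proportion.
ESOL_COEF = {"intercept": 0.16, "logp": -0.63, "mw": -0.0062, "rotb": 0.066, "ap": -0.74}
# Ali et al. TPSA model coefficients (config-overridable).
ALI_COEF = {"intercept": 0.4654, "logp": -1.0364, "tpsa": -0.0210}
# Potts-Guy skin permeability, Kp in cm/h; converted to cm/s on output.
POTTS_GUY_COEF = {"intercept": -2.74, "logp": 0.71, "mw": -0.0061}
_LOG10_S_PER_H = math.log10(3600.0)


def esol_logS(d: DescriptorSet, logp: float) -> float:
    """ESOL aqueous solubility (log10 mol/l) with a pluggable log P."""
    aromatic_proportion = (
        d.aromatic_heavy_atoms / d.heavy_atoms if d.heavy_atoms else 0.0
    )
    return (
        ESOL_COEF["intercept"]
        + ESOL_COEF["logp"] * logp
        + ESOL_COEF["mw"] * d.mw
        + ESOL_COEF["rotb"] * d.rotatable_bonds
        + ESOL_COEF["ap"] * aromatic_proportion
    )


def ali_logS(d: DescriptorSet, logp: float) -> float:
    """Ali topological solubility (log10 mol/l): linear in log P and TPSA."""
    return (
        ALI_COEF["intercept"]
        + ALI_COEF["logp"] * logp
        + ALI_COEF["tpsa"] * d.tpsa
    )


def fragment_logS(
    m: Molecule | Chem.Mol, table: FragmentTable | None, mw: float | None = None
) -> float:
    """Fragmental solubility: fragment-count sum modulated by sqrt(MW).

    logS = intercept + (sum of fragment coefficient x match count) / sqrt(MW).
    A molecule matching no fragment returns the intercept alone.
    """
    if table is None:
        raise MissingTable("no fragment log S coefficient table supplied")
    mol = _as_mol(m)
    if mw is None:
        from rdkit.Chem.Descriptors import MolWt

        mw = MolWt(mol)
    frag_sum = 0.0
    for patt, coef in table._compiled:
        frag_sum += coef * len(mol.GetSubstructMatches(patt))
    return table.intercept + frag_sum / math.sqrt(mw)


def solubility_class(logS: float) -> str:
    """Qualitative solubility label; boundary values take the more soluble side."""
    for bound, label in zip(SOLUBILITY_CLASS_BOUNDS, SOLUBILITY_CLASS_LABELS):
        if logS < bound:
            return label
    return SOLUBILITY_CLASS_LABELS[-1]


def logS_to_amounts(logS: float, mw: float) -> tuple[float, float]:
    """Convert log S to (mol/l, mg/ml)."""
    mol_per_l = 10.0 ** logS
    return mol_per_l, mol_per_l * mw


@dataclass
class SolubilityPrediction:
    """One model's solubility estimate with unit conversions and class."""

    model: str
    logS: float
    solubility_mol_per_l: float
    solubility_mg_per_ml: float
    class_label: str

    @classmethod
    def from_logS(cls, model: str, logS: float, mw: float) -> "SolubilityPrediction":
        mol_l, mg_ml = logS_to_amounts(logS, mw)
        return cls(model, logS, mol_l, mg_ml, solubility_class(logS))


def skin_log_kp(d: DescriptorSet, logp: float) -> float:
    """Potts-Guy skin permeability coefficient, log10(Kp / (cm/s))."""
    log_kp_cm_h = (
        POTTS_GUY_COEF["intercept"]
        + POTTS_GUY_COEF["logp"] * logp
        + POTTS_GUY_COEF["mw"] * d.mw
    )
    return log_kp_cm_h - _LOG10_S_PER_H


# --------------------------------------------------------------------------
# BOILED-Egg
# --------------------------------------------------------------------------

class MissingGeometry(ValueError):
    """No egg geometry configuration available."""


@dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse in the (TPSA, WLOGP) plane."""

    cx: float
    cy: float
    rx: float
    ry: float
    rotation: float = 0.0  # radians

    def contains(self, x: float, y: float) -> bool:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        dx, dy = x - self.cx, y - self.cy
        u = (c * dx + s * dy) / self.rx
        v = (-s * dx + c * dy) / self.ry
        return u * u + v * v <= 1.0


@dataclass(frozen=True)
class EggGeometry:
    """White (HIA) and yolk (BBB) ellipses plus the plot range."""

    white: Ellipse
    yolk: Ellipse
    tpsa_range: tuple[float, float]
    wlogp_range: tuple[float, float]

    @classmethod
    def from_file(cls, path) -> "EggGeometry":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "EggGeometry":
        def ell(d):
            return Ellipse(
                cx=float(d["cx"]),
                cy=float(d["cy"]),
                rx=float(d["rx"]),
                ry=float(d["ry"]),
                rotation=float(d.get("rotation", 0.0)),
            )

        return cls(
            white=ell(cfg["white"]),
            yolk=ell(cfg["yolk"]),
            tpsa_range=tuple(float(v) for v in cfg["tpsa_range"]),
            wlogp_range=tuple(float(v) for v in cfg["wlogp_range"]),
        )

    @classmethod
    def default(cls) -> "EggGeometry":
        from .config import default_egg_geometry

        return default_egg_geometry()


@dataclass
class PKProfile:
    """Pharmacokinetic readouts for one molecule."""

    log_kp: float
    hia: bool
    bbb: bool
    in_plot_range: bool
    pgp_substrate: bool | None = None


def boiled_egg(
    tpsa: float, wlogp: float, geom: EggGeometry | None = None
) -> dict[str, bool]:
    """Classify HIA (white) and BBB (yolk) from the (TPSA, WLOGP) position.

    Points outside the plot range are flagged and classified negative for
    both readouts. The two regions are not mutually exclusive.
    """
    if geom is None:
        raise MissingGeometry("no BOILED-Egg geometry supplied")
    in_range = (
        geom.tpsa_range[0] <= tpsa <= geom.tpsa_range[1]
        and geom.wlogp_range[0] <= wlogp <= geom.wlogp_range[1]
    )
    if not in_range:
        return {"hia": False, "bbb": False, "in_plot_range": False}
    return {
        "hia": geom.white.contains(tpsa, wlogp),
        "bbb": geom.yolk.contains(tpsa, wlogp),
        "in_plot_range": True,
    }
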