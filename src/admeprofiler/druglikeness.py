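"""Rule-based drug-likeness filters, bioavailability score and radar.

Each filter is a pure function of the descriptor panel plus its designated
lipophilicity descriptor (Lipinski uses MLOGP, Ghose and Egan use WLOGP,
Muegge and the radar use the XLOGP3-style pluggable slot). Thresholds live
in the packaged configuration and every breached sub-rule is reported as a
human-readable violation string.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import config
from .descriptors import DescriptorSet


@dataclass
class FilterResult:
    """Outcome of one rule-based filter."""

    name: str
    passed: bool
    violations: list[str] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def lipinski(d: DescriptorSet, mlogp: float, thresholds: dict | None = None) -> FilterResult:
    """Lipinski rule-of-five with MLOGP as the lipophilicity descriptor.

    Following the rule-of-five convention, a molecule passes with at most
    one violation; the individual breaches are always listed.
    """
    t = thresholds or config.filter_thresholds("lipinski")
    v = []
    if d.mw > t["mw_max"]:
        v.append(f"MW {d.mw:.2f} > {t['mw_max']:g}")
    if mlogp > t["mlogp_max"]:
        v.append(f"MLOGP {mlogp:.2f} > {t['mlogp_max']:g}")
    if d.hbd > t["hbd_max"]:
        v.append(f"HBD {d.hbd} > {t['hbd_max']}")
    if d.hba > t["hba_max"]:
        v.append(f"HBA {d.hba} > {t['hba_max']}")
    return FilterResult("Lipinski", len(v) <= t["max_violations_for_pass"], v)


def ghose(d: DescriptorSet, wlogp: float, thresholds: dict | None = None) -> FilterResult:
    """Ghose filter (WLOGP lipophilicity); range boundaries are inclusive."""
    t = thresholds or config.filter_thresholds("ghose")
    v = []
    if not t["mw_min"] <= d.mw <= t["mw_max"]:
        v.append(f"MW {d.mw:.2f} outside [{t['mw_min']:g}, {t['mw_max']:g}]")
    if not t["wlogp_min"] <= wlogp <= t["wlogp_max"]:
        v.append(f"WLOGP {wlogp:.2f} outside [{t['wlogp_min']:g}, {t['wlogp_max']:g}]")
    if not t["mr_min"] <= d.mr <= t["mr_max"]:
        v.append(f"MR {d.mr:.2f} outside [{t['mr_min']:g}, {t['mr_max']:g}]")
    if not t["atoms_min"] <= d.total_atoms <= t["atoms_max"]:
        v.append(f"atoms {d.total_atoms} outside [{t['atoms_min']}, {t['atoms_max']}]")
    return FilterResult("Ghose", not v, v)


def veber(d: DescriptorSet, thresholds: dict | None = None) -> FilterResult:
    """Veber filter: rotatable bonds and TPSA ceilings."""
    t = thresholds or config.filter_thresholds("veber")
    v = []
    if d.rotatable_bonds > t["rotatable_bonds_max"]:
        v.append(f"rotatable bonds {d.rotatable_bonds} > {t['rotatable_bonds_max']}")
    if d.tpsa > t["tpsa_max"]:
        v.append(f"TPSA {d.tpsa:.2f} > {t['tpsa_max']:g}")
    return FilterResult("Veber", not v, v)


def egan(d: DescriptorSet, wlogp: float, thresholds: dict | None = None) -> FilterResult:
    """Egan filter (WLOGP in place of the closed-source ALOGP98)."""
    t = thresholds or config.filter_thresholds("egan")
    v = []
    if wlogp > t["wlogp_max"]:
        v.append(f"WLOGP {wlogp:.2f} > {t['wlogp_max']:g}")
    if d.tpsa > t["tpsa_max"]:
        v.append(f"TPSA {d.tpsa:.2f} > {t['tpsa_max']:g}")
    return FilterResult("Egan", not v, v)


def muegge(d: DescriptorSet, logp: float, thresholds: dict | None = None) -> FilterResult:
    """Muegge filter, with the XLOGP3-slot lipophilicity descriptor."""
    t = thresholds or config.filter_thresholds("muegge")
    v = []
    if not t["mw_min"] <= d.mw <= t["mw_max"]:
        v.append(f"MW {d.mw:.2f} outside [{t['mw_min']:g}, {t['mw_max']:g}]")
    if not t["logp_min"] <= logp <= t["logp_max"]:
        v.append(f"XLOGP {logp:.2f} outside [{t['logp_min']:g}, {t['logp_max']:g}]")
    if d.tpsa > t["tpsa_max"]:
        v.append(f"TPSA {d.tpsa:.2f} > {t['tpsa_max']:g}")
    if d.ring_count > t["rings_max"]:
        v.append(f"rings {d.ring_count} > {t['rings_max']}")
    if d.carbon_count <= t["carbons_min_exclusive"]:
        v.append(f"carbons {d.carbon_count} <= {t['carbons_min_exclusive']}")
    if d.heteroatoms <= t["heteroatoms_min_exclusive"]:
        v.append(f"heteroatoms {d.heteroatoms} <= {t['heteroatoms_min_exclusive']}")
    if d.rotatable_bonds > t["rotatable_bonds_max"]:
        v.append(f"rotatable bonds {d.rotatable_bonds} > {t['rotatable_bonds_max']}")
    if d.hba_strict > t["hba_max"]:
        v.append(f"HBA {d.hba_strict} > {t['hba_max']}")
    if d.hbd_strict > t["hbd_max"]:
        v.append(f"HBD {d.hbd_strict} > {t['hbd_max']}")
    return FilterResult("Muegge", not v, v)


def bioavailability_score(
    net_charge: int,
    tpsa: float,
    lipinski_result: FilterResult,
    classes: dict | None = None,
) -> float:
    """Abbott bioavailability score: one of four probability classes.

    Anions (as-input net charge < 0) are classified by TPSA; everything else
    by rule-of-five compliance. The as-input (pre-neutralization) charge is
    used, since the score was parameterized on ionization state.
    """
    c = classes or config.bioavailability_classes()
    if net_charge < 0:
        if tpsa <= c["anion_tpsa_low"]:
            return c["anion_low_tpsa"]
        if tpsa <= c["anion_tpsa_high"]:
            return c["anion_mid_tpsa"]
        return c["anion_high_tpsa"]
    return c["default_pass"] if lipinski_result.passed else c["default_fail"]


def bioavailability_class_set(classes: dict | None = None) -> set[float]:
    """The set of probability classes the score can return."""
    c = classes or config.bioavailability_classes()
    return {
        c["anion_low_tpsa"],
        c["anion_mid_tpsa"],
        c["anion_high_tpsa"],
        c["default_pass"],
        c["default_fail"],
    }


RADAR_AXES = (
    "lipophilicity",
    "size",
    "polarity",
    "insolubility",
    "insaturation",
    "flexibility",
)


@dataclass
class RadarResult:
    """Bioavailability radar: six axis values, per-axis flags, overall flag."""

    values: dict[str, float]
    in_range: dict[str, bool]

    @property
    def drug_like(self) -> bool:
        return all(self.in_range.values())

    @property
    def failing_axes(self) -> list[str]:
        return [a for a in RADAR_AXES if not self.in_range[a]]


def radar(
    d: DescriptorSet,
    lipo: float,
    esol_logS: float,
    ranges: dict | None = None,
) -> RadarResult:
    """Evaluate the six radar axes.

    Axes: lipophilicity (XLOGP3-slot value), size (MW), polarity (TPSA),
    insolubility (ESOL log S, floor -6), insaturation (fraction Csp3, at
    least 0.25) and flexibility (rotatable bonds, at most 9). Drug-like
    means every axis inside its compliant range.
    """
    r = ranges or config.radar_ranges()
    values = {
        "lipophilicity": lipo,
        "size": d.mw,
        "polarity": d.tpsa,
        "insolubility": esol_logS,
        "insaturation": d.fraction_csp3,
        "flexibility": float(d.rotatable_bonds),
    }
    in_range = {
        axis: r[axis][0] <= values[axis] <= r[axis][1] for axis in RADAR_AXES
    }
    return RadarResult(values=values, in_range=in_range)
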