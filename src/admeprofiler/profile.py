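"""Per-molecule property profiles and batch profiling.

:class:`ADMEProfiler` assembles every sub-model into one record per molecule
(the one-panel-per-molecule equivalent): descriptors, lipophilicity
predictions and consensus, three solubility models with classes and unit
conversions, skin permeation and BOILED-Egg readouts, six drug-likeness
filters, the bioavailability score, the bioavailability radar, PAINS/Brenk
alerts, leadlikeness and the synthetic-accessibility score.

The profiler is transform-shaped: ``fit`` loads catalogs, tables and
geometry (fitted attributes), ``transform`` maps a batch of SMILES to a
pandas DataFrame with a stable column schema. A failing molecule yields an
error row, never an aborted batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import chemio, config, descriptors, druglikeness, lipophilicity, medchem_sa, solubility_pk
from .chemio import Molecule, MoleculeInput
from .descriptors import DescriptorSet
from .druglikeness import FilterResult, RadarResult
from .lipophilicity import LipophilicityProfile
from .medchem_sa import SAScore
from .solubility_pk import EggGeometry, PKProfile, SolubilityPrediction


@dataclass
class PropertyProfile:
    """The full computed record for one molecule."""

    name: str
    input_smiles: str
    status: str = "OK"
    error: str = ""
    canonical_smiles: str = ""
    descriptors: DescriptorSet | None = None
    lipophilicity: LipophilicityProfile | None = None
    lipo_slot_value: float | None = None
    lipo_slot_source: str = ""
    solubility: dict[str, SolubilityPrediction] = field(default_factory=dict)
    pk: PKProfile | None = None
    filters: dict[str, FilterResult] = field(default_factory=dict)
    bioavailability_score: float | None = None
    radar: RadarResult | None = None
    alerts: dict[str, list] = field(default_factory=dict)
    leadlikeness: FilterResult | None = None
    sa: SAScore | None = None
    input_net_charge: int | None = None

    def to_row(self) -> dict:
        """Flatten into a CSV-ready record with a deterministic key order."""
        row: dict = {
            "name": self.name,
            "input_smiles": self.input_smiles,
            "status": self.status,
            "error": self.error,
            "canonical_smiles": self.canonical_smiles,
            "input_net_charge": self.input_net_charge,
        }
        d = self.descriptors
        for key in (
            "mw", "heavy_atoms", "aromatic_heavy_atoms", "fraction_csp3",
            "rotatable_bonds", "hba", "hbd", "mr", "tpsa", "formal_charge",
            "ring_count", "heteroatoms", "carbon_count",
        ):
            row[key] = getattr(d, key) if d is not None else None
        lp = self.lipophilicity
        row["wlogp"] = lp.wlogp if lp else None
        row["mlogp"] = lp.mlogp if lp else None
        row["fragment_logp"] = lp.fragment_logp if lp else None
        for ext in ("XLOGP3", "ILOGP"):
            row[f"external_{ext.lower()}"] = lp.external.get(ext) if lp else None
        row["consensus_logp"] = lp.consensus if lp and lp.available() else None
        row["logp_contributors"] = lp.n_contributors if lp else None
        row["lipo_slot_value"] = self.lipo_slot_value
        row["lipo_slot_source"] = self.lipo_slot_source
        for model in ("esol", "ali", "fragmental"):
            sp = self.solubility.get(model)
            row[f"logs_{model}"] = sp.logS if sp else None
            row[f"sol_class_{model}"] = sp.class_label if sp else ""
            row[f"sol_mg_ml_{model}"] = sp.solubility_mg_per_ml if sp else None
        pk = self.pk
        row["log_kp_cm_s"] = pk.log_kp if pk else None
        row["boiled_egg_hia"] = pk.hia if pk else None
        row["boiled_egg_bbb"] = pk.bbb if pk else None
        row["egg_in_plot_range"] = pk.in_plot_range if pk else None
        row["pgp_substrate"] = pk.pgp_substrate if pk else None
        for fname in ("Lipinski", "Ghose", "Veber", "Egan", "Muegge"):
            fr = self.filters.get(fname)
            row[f"{fname.lower()}_pass"] = fr.passed if fr else None
            row[f"{fname.lower()}_violations"] = (
                "; ".join(fr.violations) if fr else ""
            )
        row["bioavailability_score"] = self.bioavailability_score
        rr = self.radar
        for axis in druglikeness.RADAR_AXES:
            row[f"radar_{axis}"] = rr.values[axis] if rr else None
            row[f"radar_{axis}_ok"] = rr.in_range[axis] if rr else None
        row["radar_drug_like"] = rr.drug_like if rr else None
        for cat in ("PAINS", "BRENK"):
            hits = self.alerts.get(cat)
            row[f"{cat.lower()}_alerts"] = len(hits) if hits is not None else None
            row[f"{cat.lower()}_alert_names"] = (
                "; ".join(h.description for h in hits) if hits else ""
            )
        row["leadlikeness_pass"] = self.leadlikeness.passed if self.leadlikeness else None
        row["leadlikeness_violations"] = (
            "; ".join(self.leadlikeness.violations) if self.leadlikeness else ""
        )
        row["sa_score"] = self.sa.normalized if self.sa else None
        return row


class ADMEProfiler(BaseEstimator, TransformerMixin):
    """Batch small-molecule profiler with a stable tabular output schema.

    Parameters
    ----------
    external_values : mapping molecule-name -> {predictor-name: value}
        Externally computed lipophilicity predictions (e.g. XLOGP3) merged
        into the consensus and used for the XLOGP3-preferring slot.
    lipo_slot_prefer : which external predictor the pluggable lipophilicity
        slot prefers before falling back to WLOGP.
    with_catalogs, with_sa : toggle alert screening / SA scoring.
    pgp_model, pgp_featurizer : optional fitted classifier and a callable
        mapping a standardized molecule to its feature vector; when absent
        the P-gp column stays empty rather than fabricated.
    """

    def __init__(
        self,
        external_values: dict | None = None,
        lipo_slot_prefer: str = "XLOGP3",
        with_catalogs: bool = True,
        with_sa: bool = True,
        fragment_logp_table: object | None = None,
        fragment_logs_table: object | None = None,
        egg_geometry: EggGeometry | None = None,
        sa_table: object | None = None,
        pgp_model: object | None = None,
        pgp_featurizer: object | None = None,
    ):
        self.external_values = external_values
        self.lipo_slot_prefer = lipo_slot_prefer
        self.with_catalogs = with_catalogs
        self.with_sa = with_sa
        self.fragment_logp_table = fragment_logp_table
        self.fragment_logs_table = fragment_logs_table
        self.egg_geometry = egg_geometry
        self.sa_table = sa_table
        self.pgp_model = pgp_model
        self.pgp_featurizer = pgp_featurizer

    def fit(self, X=None, y=None):
        """Load catalogs, coefficient tables and geometry."""
        self.flogp_table_ = (
            self.fragment_logp_table
            if self.fragment_logp_table is not None
            else config.default_fragment_logp_table()
        )
        self.flogs_table_ = (
            self.fragment_logs_table
            if self.fragment_logs_table is not None
            else config.default_fragment_logs_table()
        )
        self.egg_ = (
            self.egg_geometry if self.egg_geometry is not None else EggGeometry.default()
        )
        if self.with_catalogs:
            self.catalogs_ = {
                "PAINS": medchem_sa.builtin_catalog("PAINS"),
                "BRENK": medchem_sa.builtin_catalog("BRENK"),
            }
        else:
            self.catalogs_ = {}
        if self.with_sa:
            self.sa_table_ = (
                self.sa_table if self.sa_table is not None else medchem_sa.default_sa_table()
            )
        else:
            self.sa_table_ = None
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "egg_"):
            self.fit()

    def profile_one(self, inp: MoleculeInput | str) -> PropertyProfile:
        """Compute the full profile of one molecule; errors go to the status."""
        self._ensure_fitted()
        if isinstance(inp, str):
            inp = MoleculeInput(smiles=inp, name="Molecule_1")
        prof = PropertyProfile(name=inp.name, input_smiles=inp.smiles)
        try:
            mol = chemio.standardize(inp)
        except (chemio.InvalidSmiles, chemio.SanitizationError) as exc:
            prof.status = "ERROR"
            prof.error = str(exc)
            return prof

        prof.canonical_smiles = chemio.canonical_smiles(mol)
        prof.input_net_charge = mol.input_net_charge
        d = descriptors.compute_descriptor_panel(mol)
        prof.descriptors = d

        ext = {}
        if self.external_values:
            ext = dict(self.external_values.get(mol.name, {}))
        lp = lipophilicity.lipophilicity_profile(
            mol, table=self.flogp_table_, external=ext
        )
        prof.lipophilicity = lp
        slot, source = lp.lipo_slot(self.lipo_slot_prefer)
        prof.lipo_slot_value, prof.lipo_slot_source = slot, source

        esol = solubility_pk.esol_logS(d, slot)
        ali = solubility_pk.ali_logS(d, slot)
        prof.solubility["esol"] = SolubilityPrediction.from_logS("esol", esol, d.mw)
        prof.solubility["ali"] = SolubilityPrediction.from_logS("ali", ali, d.mw)
        try:
            fr = solubility_pk.fragment_logS(mol, self.flogs_table_, mw=d.mw)
            prof.solubility["fragmental"] = SolubilityPrediction.from_logS(
                "fragmental", fr, d.mw
            )
        except lipophilicity.MissingTable:
            pass

        egg = solubility_pk.boiled_egg(d.tpsa, lp.wlogp, self.egg_)
        pgp = None
        if self.pgp_model is not None and self.pgp_featurizer is not None:
            pgp = bool(self.pgp_model.predict([self.pgp_featurizer(mol)])[0])
        prof.pk = PKProfile(
            log_kp=solubility_pk.skin_log_kp(d, slot),
            hia=egg["hia"],
            bbb=egg["bbb"],
            in_plot_range=egg["in_plot_range"],
            pgp_substrate=pgp,
        )

        lip = druglikeness.lipinski(d, lp.mlogp)
        prof.filters = {
            "Lipinski": lip,
            "Ghose": druglikeness.ghose(d, lp.wlogp),
            "Veber": druglikeness.veber(d),
            "Egan": druglikeness.egan(d, lp.wlogp),
            "Muegge": druglikeness.muegge(d, slot),
        }
        prof.bioavailability_score = druglikeness.bioavailability_score(
            mol.input_net_charge, d.tpsa, lip
        )
        prof.radar = druglikeness.radar(d, slot, esol)

        for cat_name, cat in self.catalogs_.items():
            prof.alerts[cat_name] = medchem_sa.screen(mol, cat)
        prof.leadlikeness = medchem_sa.leadlikeness(d, slot)
        if self.sa_table_ is not None:
            prof.sa = medchem_sa.sa_score(mol, self.sa_table_)
        return prof

    def profile_batch(self, inputs: Iterable[MoleculeInput | str]) -> list[PropertyProfile]:
        return [self.profile_one(inp) for inp in inputs]

    def transform(self, X) -> pd.DataFrame:
        """Profile a batch (iterable of SMILES / MoleculeInput, or multiline text)."""
        if isinstance(X, str):
            X = chemio.parse_input_list(X)
        profiles = self.profile_batch(X)
        return pd.DataFrame([p.to_row() for p in profiles])


def egg_plot_data(profiles: list[PropertyProfile]) -> pd.DataFrame:
    """BOILED-Egg plot table: one row per molecule with readout flags.

    ``pgp_flag`` stays empty (pandas NA) when no P-gp model was loaded.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "name": p.name,
                "tpsa": p.descriptors.tpsa if p.descriptors else None,
                "wlogp": p.lipophilicity.wlogp if p.lipophilicity else None,
                "hia": p.pk.hia if p.pk else None,
                "bbb": p.pk.bbb if p.pk else None,
                "pgp_flag": p.pk.pgp_substrate if p.pk else None,
                "in_range": p.pk.in_plot_range if p.pk else None,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n_outside_range"] = int((frame["in_range"] == False).sum())  # noqa: E712
    return frame
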