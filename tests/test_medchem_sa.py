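"""Structural-alert screening, leadlikeness and the SA score."""

import math

import numpy as np
import pytest

from admeprofiler import build_frequency_table, sa_score, screen, standardize
from admeprofiler import medchem_sa as mc
from admeprofiler.descriptors import fp2_fingerprint
from admeprofiler.medchem_sa import (
    BadPattern,
    CountMismatch,
    DialectMismatch,
    EmptyLibrary,
    FragmentFrequencyTable,
    benchmark_statistics,
    builtin_catalog,
    leadlikeness,
    load_catalog,
)
from tests.conftest import random_molecules
from tests.test_druglikeness import _stub


@pytest.fixture(scope="module")
def pains():
    return builtin_catalog("PAINS")


@pytest.fixture(scope="module")
def brenk():
    return builtin_catalog("BRENK")


@pytest.fixture(scope="module")
def mini_table():
    return mc.default_sa_table()


class TestCatalogs:
    def test_brenk_catalog_has_105_patterns(self, brenk):
        assert len(brenk) == 105

    def test_curated_pains_catalog_has_480_patterns(self, pains):
        # RDKit's curated Baell collection (16 A + 55 B + 409 C)
        assert len(pains) == 480

    def test_file_loader_roundtrip_and_count_check(self, tmp_path):
        path = tmp_path / "cat.smarts"
        path.write_text("[OX2H]\thydroxyl\nc1ccccc1\tbenzene ring\n")
        cat = load_catalog(path, expected_count=2)
        assert len(cat) == 2 and cat.entries[0][1] == "hydroxyl"
        with pytest.raises(CountMismatch):
            load_catalog(path, expected_count=3)

    def test_invalid_smarts_names_the_line(self, tmp_path):
        path = tmp_path / "bad.smarts"
        path.write_text("[OX2H]\tok\n[QQ\tbroken\n")
        with pytest.raises(BadPattern, match=":2"):
            load_catalog(path)


class TestScreening:
    def test_methane_triggers_no_alert(self, pains, brenk):
        m = standardize("C")
        assert screen(m, pains) == [] and screen(m, brenk) == []

    def test_para_quinone_is_a_pains_hit(self, pains):
        hits = screen(standardize("O=C1C=CC(=O)C=C1"), pains)
        assert len(hits) >= 1
        assert any("quinone" in h.description.lower() for h in hits)

    def test_hit_count_invariant_under_renumbering(self, pains, brenk):
        a = standardize("O=C1C=CC(=O)C=C1c1ccccc1N")
        b = standardize("Nc1ccccc1C1=CC(=O)C=CC1=O")
        for cat in (pains, brenk):
            assert [h.description for h in screen(a, cat)] == [
                h.description for h in screen(b, cat)
            ]

    def test_file_catalog_screening(self, tmp_path):
        path = tmp_path / "cat.smarts"
        path.write_text("[OX2H]\thydroxyl\n[NX3;H2]\tprimary amine\n")
        cat = load_catalog(path)
        hits = screen(standardize("NCCO"), cat)
        assert [h.description for h in hits] == ["hydroxyl", "primary amine"]


class TestLeadlikeness:
    def test_mid_sized_lead_passes(self):
        assert leadlikeness(_stub(mw=300.0, rotatable_bonds=4), logp=2.0).passed

    def test_mw_500_fails_size_window(self):
        r = leadlikeness(_stub(mw=500.0), logp=2.0)
        assert any("MW" in v for v in r.violations)

    @pytest.mark.parametrize(
        "kw,logp,expected_substring",
        [
            ({"mw": 400.0}, 2.0, "MW"),
            ({}, 3.6, "XLOGP"),
            ({"rotatable_bonds": 8}, 2.0, "rotatable"),
        ],
    )
    def test_each_threshold_breached_singly(self, kw, logp, expected_substring):
        r = leadlikeness(_stub(**kw), logp=logp)
        assert r.n_violations == 1 and expected_substring in r.violations[0]


class TestFrequencyTable:
    def test_single_molecule_library_bits_contribute_zero(self):
        table = build_frequency_table(["CCO"], calibrate=False)
        bits = np.flatnonzero(fp2_fingerprint(standardize("CCO")))
        assert np.allclose(table.contributions[bits], 0.0)

    def test_most_frequent_bit_contributes_zero(self, mini_table):
        assert mini_table.contributions.max() == pytest.approx(0.0)

    def test_unseen_bits_carry_floor_penalty(self):
        table = build_frequency_table(["CCO"], calibrate=False)
        floor = math.log(0.5 / table.max_count)
        unseen = table.contributions == floor
        assert unseen.sum() == 1024 - fp2_fingerprint(standardize("CCO")).sum()

    def test_counts_match_brute_force_recount(self):
        smiles = ["CCO", "CCN", "c1ccccc1O", "CC(=O)OC", "CCO"]
        table = build_frequency_table(smiles, calibrate=False)
        recount = np.zeros(1024, dtype=int)
        for s in smiles:
            recount += fp2_fingerprint(standardize(s)).astype(int)
        observed = recount > 0
        assert np.allclose(
            table.contributions[observed], np.log(recount[observed] / recount.max())
        )

    def test_order_invariant(self):
        smiles = ["CCO", "CCN", "c1ccccc1O", "CC(=O)OC"]
        a = build_frequency_table(smiles)
        b = build_frequency_table(smiles[::-1])
        assert np.allclose(a.contributions, b.contributions)
        assert (a.raw_min, a.raw_max) == (b.raw_min, b.raw_max)

    def test_empty_library_raises(self):
        with pytest.raises(EmptyLibrary):
            build_frequency_table([])

    def test_json_round_trip(self, tmp_path, mini_table):
        path = tmp_path / "table.json"
        mini_table.save(path)
        back = FragmentFrequencyTable.load(path)
        assert back.library_size == mini_table.library_size
        assert back.dialect == mini_table.dialect
        assert np.allclose(back.contributions, mini_table.contributions, atol=1e-6)


class TestSAScore:
    def test_normalized_in_range_on_random_sweep(self, mini_table):
        for smi in random_molecules(1000, seed=5):
            s = sa_score(standardize(smi), mini_table)
            assert 1.0 <= s.normalized <= 10.0

    def test_monotone_in_fragment_rarity(self, mini_table):
        m = standardize("CC(=O)Oc1ccccc1C(=O)O")
        base = sa_score(m, mini_table)
        rarer = FragmentFrequencyTable(
            contributions=mini_table.contributions - 1.0,
            library_size=mini_table.library_size,
            max_count=mini_table.max_count,
            raw_min=mini_table.raw_min,
            raw_max=mini_table.raw_max,
        )
        assert sa_score(m, rarer).normalized >= base.normalized

    def test_penalties_nonnegative_and_raise_score(self, mini_table):
        flat = standardize("CCCCCCCC")
        bridged = standardize("C1CC2CCC1C2")
        s_flat, s_bridged = sa_score(flat, mini_table), sa_score(bridged, mini_table)
        for s in (s_flat, s_bridged):
            for pen in ("size_penalty", "chiral_penalty", "spiro_penalty", "bridge_penalty", "macrocycle_penalty"):
                assert getattr(s, pen) >= 0.0
        assert s_bridged.bridge_penalty > 0.0
        assert sa_score(standardize("O=C1CCCCCCCCCCC1"), mini_table).macrocycle_penalty > 0

    def test_max_frequency_fragments_score_easy_extreme(self):
        # library of one molecule: its own bits all contribute 0
        table = build_frequency_table(["CCO"])
        s = sa_score(standardize("CCO"), table)
        assert s.fragment_term == pytest.approx(0.0)
        assert s.normalized <= 2.0

    def test_dialect_mismatch_rejected(self, mini_table):
        alien = FragmentFrequencyTable(
            contributions=mini_table.contributions,
            library_size=1,
            max_count=1,
            dialect="other/0",
        )
        with pytest.raises(DialectMismatch):
            sa_score(standardize("CCO"), alien)


class TestBenchmarkHarness:
    def test_statistics_on_known_values(self):
        stats = benchmark_statistics([1.0, 2.0, 4.0], [1.0, 3.0, 3.0])
        assert stats["mae"] == pytest.approx(2 / 3)
        assert stats["rmse"] == pytest.approx(math.sqrt(2 / 3))
        assert -1.0 <= stats["r"] <= 1.0

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            benchmark_statistics([1.0], [1.0, 2.0])
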