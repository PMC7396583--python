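"""Lipid nomenclature parsing, class aggregation, DBI, RC tables, FFA summaries."""

import numpy as np
import pandas as pd
import pytest

from coldomics import lipidomics as lip
from coldomics.physiology import relative_change


def _profile(conc: dict[str, dict[str, float]]) -> lip.LipidProfile:
    """Build a profile from {species: {group: mean}} with two replicates per group."""
    groups = sorted({g for v in conc.values() for g in v})
    rows, meta_rows = {}, []
    for g in groups:
        genotype, condition = g.rsplit("-", 1)
        for r in (1, 2):
            sid = f"{genotype}_{condition}_r{r}"
            meta_rows.append({"sample_id": sid, "genotype": genotype,
                              "condition": condition, "replicate": r})
            rows[sid] = [conc[s].get(g, 0.0) for s in conc]
    values = pd.DataFrame(rows, index=list(conc))
    meta = pd.DataFrame(meta_rows).drop_duplicates("sample_id").set_index("sample_id")
    return lip.LipidProfile(values, meta)


class TestParser:
    @pytest.mark.parametrize(
        "name, klass, carbons, db",
        [
            ("C36:6-MGDG", "MGDG", 36, 6),
            ("C34:6-DGDG", "DGDG", 34, 6),
            ("18:3/18:0-DAG", "DAG", 36, 3),
            ("18:2/16:1-DAG", "DAG", 34, 3),
            ("d18:1/24:0-Cer", "Cer", 42, 1),
            ("t18:1/h22:0-GluCer", "GluCer", 40, 1),
            ("d18:1-S1P", "S1P", 18, 1),
            ("C52:3-TAG", "TAG", 52, 3),
        ],
    )
    def test_three_dialects(self, name, klass, carbons, db):
        sp = lip.parse_species(name)
        assert sp.lipid_class == klass
        assert sp.total_carbons == carbons
        assert sp.double_bonds == db

    def test_chain_totals_consistent_with_chain_fields(self):
        sp = lip.parse_species("t18:1/h22:0-GluCer")
        assert sp.chains == ((18, 1, "t"), (22, 0, "h"))
        assert sum(c for c, _, _ in sp.chains) == sp.total_carbons
        assert sum(d for _, d, _ in sp.chains) == sp.double_bonds

    @pytest.mark.parametrize("bad", ["", "C36:6-XYZ", "18:2|16:0-DAG", "C36-MGDG", "MGDG"])
    def test_malformed_names_rejected_naming_token(self, bad):
        with pytest.raises(ValueError):
            lip.parse_species(bad)


class TestClassTotals:
    def test_single_species_class_total(self):
        p = _profile({"C36:6-MGDG": {"nh5-control": 7.5, "nh5-cold": 6.0}})
        ct = lip.class_totals(p).set_index(["class", "condition"])["mean"]
        assert ct[("MGDG", "control")] == pytest.approx(7.5)
        assert ct[("Total", "cold")] == pytest.approx(6.0)

    def test_totals_invariant_to_species_splitting(self):
        whole = _profile({"C36:6-MGDG": {"g-control": 8.0}, "C34:1-PC": {"g-control": 4.0}})
        split = _profile(
            {"C36:6-MGDG": {"g-control": 5.0}, "C36:6-DGDG": {"g-control": 0.0},
             "C34:6-MGDG": {"g-control": 3.0}, "C34:1-PC": {"g-control": 4.0}}
        )
        t1 = lip.class_totals(whole).set_index(["class", "condition"])["mean"]
        t2 = lip.class_totals(split).set_index(["class", "condition"])["mean"]
        assert t1[("Total", "control")] == t2[("Total", "control")]
        assert t1[("MGDG", "control")] == t2[("MGDG", "control")]

    def test_negative_concentration_rejected(self):
        values = pd.DataFrame({"s1": [-1.0]}, index=["C36:6-MGDG"])
        meta = pd.DataFrame(
            [{"sample_id": "s1", "genotype": "g", "condition": "control", "replicate": 1}]
        ).set_index("sample_id")
        with pytest.raises(ValueError):
            lip.LipidProfile(values, meta)


class TestDbi:
    def test_single_species_limit_equals_its_double_bonds(self):
        p = _profile({"C36:6-MGDG": {"g-control": 3.0, "g-cold": 3.0}})
        d = lip.dbi(p)
        assert d.loc["MGDG", "g-control"] == pytest.approx(6.0)
        assert d.loc["Total", "g-control"] == pytest.approx(6.0)

    def test_scale_invariance_under_global_rescaling(self):
        conc = {"C36:6-MGDG": {"g-control": 3.0}, "C34:2-PC": {"g-control": 1.5},
                "d18:1/24:0-Cer": {"g-control": 0.25}}
        doubled = {k: {g: 2 * v for g, v in vals.items()} for k, vals in conc.items()}
        d1 = lip.dbi(_profile(conc))
        d2 = lip.dbi(_profile(doubled))
        pd.testing.assert_frame_equal(d1, d2)

    def test_total_row_is_exact_sum_of_class_rows(self):
        conc = {"C36:6-MGDG": {"g-control": 3.0}, "C34:2-PC": {"g-control": 1.5},
                "C34:1-PG": {"g-control": 0.7}, "d18:1/24:0-Cer": {"g-control": 0.25}}
        d = lip.dbi(_profile(conc))
        assert d.loc["Total", "g-control"] == pytest.approx(
            d.drop("Total").sum()["g-control"], abs=1e-12
        )

    def test_storage_classes_excluded_from_default_panel(self):
        conc = {"C36:6-MGDG": {"g-control": 1.0}, "C52:3-TAG": {"g-control": 100.0}}
        d = lip.dbi(_profile(conc))
        # the TAG mass must not dilute the membrane DBI
        assert d.loc["MGDG", "g-control"] == pytest.approx(6.0)
        assert "TAG" not in d.index


class TestReferenceDbiTable:
    """Checks against the published membrane-lipid DBI reference columns."""

    def test_sensitive_control_class_dbis_sum_to_printed_total(self, reference_dbi):
        classes = reference_dbi.drop("Total")
        assert classes["FH18-control"].sum() == pytest.approx(5.0170, abs=1e-12)

    def test_other_columns_sum_within_printing_precision(self, reference_dbi):
        classes = reference_dbi.drop("Total")
        for col in ("NH5-control", "NH5-cold", "FH18-cold"):
            assert classes[col].sum() == pytest.approx(
                reference_dbi.loc["Total", col], abs=2e-4
            )

    def test_recomputed_rc_matches_printed_rc_columns(self, reference_dbi):
        """RC from the printed DBI pairs reproduces the printed RC to 4 dp.

        Cer and S1P are excluded: their printed DBI pairs are rounded to a
        precision (4 dp, near zero) at which the printed RC is not
        recoverable (S1P is 0/0).
        """
        skip = {"Cer", "S1P"}
        for klass in reference_dbi.index:
            if klass in skip:
                continue
            for geno in ("NH5", "FH18"):
                ctrl = reference_dbi.loc[klass, f"{geno}-control"]
                cold = reference_dbi.loc[klass, f"{geno}-cold"]
                if ctrl == 0:
                    continue
                rc = relative_change(ctrl, cold)
                assert rc == pytest.approx(
                    reference_dbi.loc[klass, f"rc_{geno}"], abs=1e-4 + 1e-12
                ), klass


class TestLipidRcTable:
    def test_rc_and_stars_on_constructed_profile(self):
        p = _profile(
            {"C36:6-MGDG": {"nh5-control": 4.0, "nh5-cold": 2.0},
             "C34:2-PC": {"nh5-control": 1.0, "nh5-cold": 1.0}}
        )
        out = lip.lipid_rc_table(p).set_index("class")
        assert out.loc["MGDG", "rc_concentration"] == pytest.approx(-0.5)
        assert out.loc["PC", "rc_concentration"] == pytest.approx(0.0)

    def test_letters_separate_clearly_different_groups(self):
        rng = np.random.default_rng(1)
        rows, meta_rows = {}, []
        for g, mean in (("nh5", 10.0), ("fh18", 1.0)):
            for cond in ("control", "cold"):
                for r in range(1, 5):
                    sid = f"{g}_{cond}_r{r}"
                    meta_rows.append({"sample_id": sid, "genotype": g,
                                      "condition": cond, "replicate": r})
                    rows[sid] = [mean + rng.normal(0, 0.1)]
        p = lip.LipidProfile(pd.DataFrame(rows, index=["C36:6-MGDG"]),
                             pd.DataFrame(meta_rows).set_index("sample_id"))
        out = lip.lipid_rc_table(p)
        mg = out[out["class"] == "MGDG"].set_index("genotype")
        assert mg.loc["nh5", "letters_control"] != mg.loc["fh18", "letters_control"]


class TestDagTagRatio:
    def test_simple_ratio(self):
        p = _profile({"18:2/16:0-DAG": {"g-control": 2.0, "g-cold": 2.0},
                      "C52:3-TAG": {"g-control": 4.0, "g-cold": 2.0}})
        out = lip.dag_tag_ratio(p).set_index("genotype")
        assert out.loc["g", "ratio_control"] == pytest.approx(0.5)
        assert out.loc["g", "ratio_cold"] == pytest.approx(1.0)

    def test_tolerant_like_effect_decreases_ratio(self):
        # TAG rises more than DAG under cold: the ratio must fall
        p = _profile({"18:2/16:0-DAG": {"g-control": 2.0, "g-cold": 2.4},
                      "C52:3-TAG": {"g-control": 4.0, "g-cold": 6.0}})
        out = lip.dag_tag_ratio(p).set_index("genotype")
        assert out.loc["g", "rc"] < 0


class TestFfa:
    @pytest.mark.parametrize("db, expected", [(0, "SFA"), (1, "MUFA"), (2, "PUFA"), (6, "PUFA")])
    def test_saturation_classification(self, db, expected):
        assert lip.saturation_class(db) == expected

    def test_reference_panel_saturation_sums(self, reference_ffa):
        meta_rows, cols = [], {}
        for col in reference_ffa.columns:
            genotype, condition = col.rsplit("-", 1)
            sid = f"{genotype}_{condition}"
            meta_rows.append({"sample_id": sid, "genotype": genotype,
                              "condition": condition, "replicate": 1})
            cols[sid] = reference_ffa[col].to_numpy()
        values = pd.DataFrame(cols, index=reference_ffa.index)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        s = lip.ffa_summary(values, meta).set_index("genotype")
        assert s.loc["NH5", "pufa_control"] == pytest.approx(392.55, abs=1e-9)
        assert s.loc["NH5", "pufa_cold"] == pytest.approx(484.22, abs=1e-9)
        assert s.loc["FH18", "pufa_control"] == pytest.approx(320.65, abs=1e-9)
        assert s.loc["FH18", "pufa_cold"] == pytest.approx(327.51, abs=1e-9)
        assert s.loc["FH18", "sfa_control"] == pytest.approx(348.00, abs=1e-9)
        # totals agree with the published rows within input rounding
        assert s.loc["NH5", "total_control"] == pytest.approx(877.90, abs=0.05)
        assert s.loc["FH18", "total_control"] == pytest.approx(780.77, abs=0.05)

    def test_all_sfa_panel_has_zero_pufa_and_ratio(self):
        values = pd.DataFrame({"g_control": [1.0, 2.0]}, index=["C16:0", "C18:0"])
        meta = pd.DataFrame(
            [{"sample_id": "g_control", "genotype": "g", "condition": "control", "replicate": 1}]
        ).set_index("sample_id")
        s = lip.ffa_summary(values, meta).set_index("genotype")
        assert s.loc["g", "pufa_control"] == 0.0
        assert s.loc["g", "pufa_sfa_ratio_control"] == 0.0

    def test_duplicate_names_rejected(self):
        values = pd.DataFrame({"s": [1.0, 1.0]}, index=["C16:0", "C16:0"])
        meta = pd.DataFrame(
            [{"sample_id": "s", "genotype": "g", "condition": "control", "replicate": 1}]
        ).set_index("sample_id")
        with pytest.raises(ValueError):
            lip.ffa_summary(values, meta)
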