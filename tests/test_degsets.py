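"""Differential-expression set construction: filters, calls, CDEGs, partition algebra."""

import numpy as np
import pandas as pd
import pytest

from coldomics import simulate
from coldomics.degsets import (
    ExpressionMatrix,
    build_partition,
    call_de,
    call_de_all,
    detect_cdeg,
    enhance_common,
    filter_expressed,
    partition,
    putative_set,
)


def _matrix(values: dict, meta_rows: list[dict]) -> ExpressionMatrix:
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    df = pd.DataFrame(values).T.rename_axis("gene")
    df.columns = list(meta.index)
    return ExpressionMatrix(df, meta)


class TestFilterExpressed:
    @staticmethod
    def _simple(fpkms):
        meta_rows = [
            {"sample_id": f"s{i}", "genotype": "tolerant", "timepoint_h": 0,
             "condition": "control", "replicate": i + 1}
            for i in range(len(next(iter(fpkms.values()))))
        ]
        return _matrix(fpkms, meta_rows)

    def test_all_zero_matrix_yields_empty_set(self):
        m = self._simple({"g1": [0, 0, 0], "g2": [0, 0, 0]})
        assert len(filter_expressed(m, 1.0)) == 0

    def test_boundary_mean_exactly_one_is_retained(self):
        m = self._simple({"g1": [1.0, 1.0, 1.0], "g2": [0.5, 0.5, 0.5]})
        kept = filter_expressed(m, 1.0, scope="any-group-mean")
        assert list(kept) == ["g1"]

    def test_zero_threshold_keeps_everything(self):
        m = self._simple({"g1": [0, 0, 0], "g2": [5, 5, 5]})
        assert set(filter_expressed(m, 0.0)) == {"g1", "g2"}

    def test_scope_semantics_differ_on_mixed_gene(self):
        m = self._simple({"g1": [3.0, 0.1, 0.1]})  # mean 1.07
        assert "g1" in filter_expressed(m, 1.0, scope="any-group-mean")
        assert "g1" in filter_expressed(m, 1.0, scope="any-sample")
        assert "g1" not in filter_expressed(m, 1.0, scope="all-samples")


class TestCallDe:
    def test_zero_noise_planted_gene_called_up_with_exact_fc(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes=30, tolerant_only_up=3, noise_sd_log=0.0, effect_log2fc=2.0, seed=0
        )
        values, meta, truth = simulate.gen_expression(cfg)
        de = call_de(ExpressionMatrix(values, meta), "tolerant", 12)
        planted = truth.labels.index[truth.labels == "tolerant_only_up"]
        sub = de.loc[planted]
        assert (sub["direction"] == "up").all()
        assert np.allclose(sub["fc"], 4.0, rtol=1e-3)  # pseudocount-negligible

    def test_identical_group_means_are_ns(self):
        cfg = simulate.ExpressionSimConfig(n_genes=20, noise_sd_log=0.0, seed=0)
        values, meta, _ = simulate.gen_expression(cfg)
        de = call_de(ExpressionMatrix(values, meta), "sensitive", 24)
        assert (de["direction"] == "ns").all()

    def test_missing_group_raises_with_contrast_name(self):
        cfg = simulate.ExpressionSimConfig(n_genes=10, seed=0)
        values, meta, _ = simulate.gen_expression(cfg)
        keep = meta.index[~((meta.genotype == "tolerant") & (meta.timepoint_h == 12)
                            & (meta.condition == "cold"))]
        m = ExpressionMatrix(values[keep], meta.loc[keep])
        with pytest.raises(ValueError, match="tolerant.*12"):
            call_de(m, "tolerant", 12)

    def test_null_simulation_controls_false_discovery_rate(self):
        """Across seeded null matrices the mean FDR<0.01 fraction stays at or below 0.01."""
        fractions = []
        for seed in range(20):
            cfg = simulate.ExpressionSimConfig(
                n_genes=300, noise_sd_log=0.25, seed=seed, timepoints=(0, 12)
            )
            values, meta, _ = simulate.gen_expression(cfg)
            de = call_de(ExpressionMatrix(values, meta), "tolerant", 12)
            fractions.append((de["fdr"] < 0.01).mean())
        assert np.mean(fractions) <= 0.01


class TestDetectCdeg:
    @staticmethod
    def _results(rows):
        return pd.DataFrame(
            [
                {"gene_id": g, "genotype": "tolerant", "timepoint_h": tp,
                 "fc": 1.0, "log2fc": 0.0, "pvalue": 1.0, "fdr": 1.0, "direction": d}
                for g, tp, d in rows
            ]
        )

    def test_any_mode_accepts_single_timepoint_hit(self):
        res = self._results([("g", 12, "up"), ("g", 24, "ns")])
        assert detect_cdeg(res, "any").to_dict() == {"g": "up"}

    def test_all_mode_requires_every_timepoint(self):
        res = self._results([("g", 12, "up"), ("g", 24, "ns")])
        assert detect_cdeg(res, "all").empty

    @pytest.mark.parametrize(
        "d12, d24, expected",
        [
            ("up", "up", "up"),
            ("down", "down", "down"),
            ("up", "down", "conflict"),
            ("down", "up", "conflict"),
            ("ns", "down", "down"),
            ("ns", "ns", None),
        ],
    )
    def test_direction_combination_enumeration(self, d12, d24, expected):
        res = self._results([("g", 12, d12), ("g", 24, d24)])
        got = detect_cdeg(res, "any")
        if expected is None:
            assert got.empty
        else:
            assert got["g"] == expected


class TestPartitionAlgebra:
    def test_disjoint_sets_have_empty_common(self):
        t = pd.Series({"a": "up", "b": "down"})
        s = pd.Series({"c": "up"})
        p = partition(t, s)
        assert p.common == frozenset()
        assert p.tolerant_only == {"a", "b"} and p.sensitive_only == {"c"}

    def test_identical_sets_have_empty_exclusives(self):
        t = pd.Series({"a": "up", "b": "down"})
        p = partition(t, t.copy())
        assert p.tolerant_only == frozenset() and p.sensitive_only == frozenset()
        assert p.common == {"a", "b"}

    def test_partition_parts_are_disjoint_and_cover_union(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            universe = [f"g{i}" for i in range(40)]
            t = pd.Series("up", index=rng.choice(universe, 15, replace=False))
            s = pd.Series("down", index=rng.choice(universe, 18, replace=False))
            p = partition(t, s)
            parts = [p.tolerant_only, p.sensitive_only, p.common]
            assert sum(len(x) for x in parts) == len(set(t.index) | set(s.index))
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not (parts[i] & parts[j])

    def test_putative_size_matches_brute_force_union_on_random_universes(self):
        """Set-algebra equivalence with an independent brute-force oracle."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            universe = [f"g{i}" for i in range(rng.integers(10, 100))]
            t_genes = {g for g in universe if rng.random() < 0.3}
            s_genes = {g for g in universe if rng.random() < 0.3}
            enhanced = {g for g in (t_genes & s_genes) if rng.random() < 0.5}
            p = partition(
                pd.Series("up", index=sorted(t_genes)),
                pd.Series("up", index=sorted(s_genes)),
            )
            p.enhanced_common = frozenset(enhanced)
            got = putative_set(p)
            # oracle: element-by-element membership listing
            expected = {g for g in universe if (g in t_genes and g not in s_genes) or g in enhanced}
            assert got == expected
            assert len(got) == len(p.tolerant_only) + len(p.enhanced_common)


class TestEnhanceCommon:
    @staticmethod
    def _de(genotype, pairs):
        return pd.DataFrame(
            [
                {"gene_id": g, "genotype": genotype, "timepoint_h": tp, "fc": 2.0**l2,
                 "log2fc": l2, "pvalue": 0.0, "fdr": 0.0, "direction": "up"}
                for g, tp, l2 in pairs
            ]
        )

    @pytest.mark.parametrize(
        "lt, ls, qualifies",
        [
            (3.0, 1.0, True),    # ratio 4
            (2.0, 2.0, False),   # equal response
            (-3.0, -1.0, True),  # magnitude rule for downregulation
            (3.0, 2.0, True),    # exact ratio 2, inclusive
            (3.0, -1.0, False),  # opposite directions never qualify
            (1.5, 3.0, False),   # stronger in the sensitive genotype
        ],
    )
    def test_sign_and_magnitude_enumeration(self, lt, ls, qualifies):
        de_t = self._de("tolerant", [("g", 12, lt)])
        de_s = self._de("sensitive", [("g", 12, ls)])
        got = enhance_common(frozenset({"g"}), de_t, de_s)
        assert (("g" in got) is qualifies)

    def test_any_vs_all_mode(self):
        de_t = self._de("tolerant", [("g", 12, 3.0), ("g", 24, 2.0)])
        de_s = self._de("sensitive", [("g", 12, 1.0), ("g", 24, 2.0)])
        assert "g" in enhance_common(frozenset({"g"}), de_t, de_s, mode="any")
        assert "g" not in enhance_common(frozenset({"g"}), de_t, de_s, mode="all")


class TestFullPipeline:
    def test_zero_noise_recovery_of_every_planted_count(self, planted_matrix, planted_config):
        m, _ = planted_matrix
        c = planted_config
        part, _ = build_partition(m)
        assert len(part.tolerant_only) == c.tolerant_only_up + c.tolerant_only_down
        assert len(part.sensitive_only) == c.sensitive_only_up + c.sensitive_only_down
        assert len(part.common) == (c.common_up + c.common_down
                                    + c.enhanced_common_up + c.enhanced_common_down)
        assert len(part.enhanced_common) == c.enhanced_common_up + c.enhanced_common_down
        assert len(part.putative) == (c.tolerant_only_up + c.tolerant_only_down
                                      + c.enhanced_common_up + c.enhanced_common_down)

    def test_up_down_tallies_equal_set_sizes(self, planted_matrix):
        m, _ = planted_matrix
        part, _ = build_partition(m)
        for _, row in part.summary().iterrows():
            assert row["up"] + row["down"] + row["conflict"] == row["size"]

    def test_raising_fc_threshold_never_enlarges_cdeg_sets(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes=200, common_up=20, tolerant_only_up=10, noise_sd_log=0.4, seed=3
        )
        values, meta, _ = simulate.gen_expression(cfg)
        m = ExpressionMatrix(values, meta)
        loose, _ = build_partition(m, fc_threshold=2.0)
        strict, _ = build_partition(m, fc_threshold=4.0)
        assert set(strict.cdeg_tolerant.index) <= set(loose.cdeg_tolerant.index)
        assert set(strict.cdeg_sensitive.index) <= set(loose.cdeg_sensitive.index)
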