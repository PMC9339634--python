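import math

import numpy as np
import pytest

from thyromine.discretize import split_by_class, table1_spec, table2_spec
from thyromine.ingest import (
    DATASET1_SELECTION, DATASET2_SELECTION, MISSING, drop_incomplete,
    select_attributes,
)
from thyromine.discretize import encode_transactions
from thyromine.synthetic_data import (
    AttributeSpec, PlantedPattern, SyntheticConfig, SyntheticConfigError,
    generate, preset_dataset1_like, preset_dataset2_like, recovery_config,
)


def two_level(name, p_a, classes=("Neg", "Pos")):
    return AttributeSpec(name=name, levels=("A", "B"),
                         probs={c: (p, 1 - p) for c, p in zip(classes, p_a)})


def basic_config(**kw):
    defaults = dict(
        n=400,
        class_levels={"Neg": 0.5, "Pos": 0.5},
        attributes=[two_level("x", (0.7, 0.3)), two_level("y", (0.5, 0.9))],
        seed=11,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestValidation:
    def test_class_proportions_must_sum_to_one(self):
        with pytest.raises(SyntheticConfigError):
            generate(basic_config(class_levels={"Neg": 0.6, "Pos": 0.6}))

    def test_level_probs_must_sum_to_one(self):
        bad = AttributeSpec("x", ("A", "B"), {"Neg": (0.7, 0.7),
                                              "Pos": (0.5, 0.5)})
        with pytest.raises(SyntheticConfigError, match="x"):
            generate(basic_config(attributes=[bad]))

    def test_pattern_above_marginal_is_infeasible(self):
        cfg = basic_config(planted_patterns=[
            PlantedPattern("Pos", {"x": "A"}, 0.5)])  # P(x=A|Pos)=0.3 < 0.5
        with pytest.raises(SyntheticConfigError, match="infeasible"):
            generate(cfg)

    def test_overlapping_patterns_rejected(self):
        cfg = basic_config(planted_patterns=[
            PlantedPattern("Neg", {"x": "A"}, 0.2),
            PlantedPattern("Neg", {"x": "B", "y": "A"}, 0.1)])
        with pytest.raises(SyntheticConfigError, match="overlap"):
            generate(cfg)

    def test_missing_rate_bounds(self):
        with pytest.raises(SyntheticConfigError):
            generate(basic_config(missing_rate=1.0))


class TestGenerate:
    def test_same_seed_identical_tables(self):
        t1, g1 = generate(basic_config())
        t2, g2 = generate(basic_config())
        assert t1.records == t2.records
        assert g1.class_counts == g2.class_counts

    def test_different_seed_differs(self):
        t1, _ = generate(basic_config())
        t2, _ = generate(basic_config(seed=12))
        assert t1.records != t2.records

    def test_class_proportions_within_binomial_error(self):
        _, truth = generate(basic_config(n=4000))
        se = math.sqrt(0.5 * 0.5 / 4000)
        assert abs(truth.class_counts["Pos"] / 4000 - 0.5) <= 3 * se

    def test_marginals_match_within_3se(self):
        cfg = basic_config(n=5000)
        table, truth = generate(cfg)
        for cl, p_a in (("Neg", 0.7), ("Pos", 0.3)):
            n_cl = truth.class_counts[cl]
            frac = truth.item_counts[cl]["x=A"] / n_cl
            se = math.sqrt(p_a * (1 - p_a) / n_cl)
            assert abs(frac - p_a) <= 3 * se

    def test_marginals_preserved_under_planting(self):
        # the residual-mixture draw must leave single-item marginals intact
        cfg = basic_config(n=8000, planted_patterns=[
            PlantedPattern("Pos", {"y": "B"}, 0.05)])  # P(y=B|Pos)=0.1
        _, truth = generate(cfg)
        n_pos = truth.class_counts["Pos"]
        frac = truth.item_counts["Pos"]["y=B"] / n_pos
        se = math.sqrt(0.1 * 0.9 / n_pos)
        assert abs(frac - 0.1) <= 3 * se

    def test_planted_pattern_support_within_3se(self):
        cfg = SyntheticConfig(
            n=5000, class_levels={"Neg": 0.0, "Pos": 1.0},
            attributes=[two_level("a", (0.5, 0.3)), two_level("b", (0.5, 0.3))],
            planted_patterns=[PlantedPattern("Pos", {"a": "B", "b": "B"}, 0.7)],
            seed=5,
        )
        _, truth = generate(cfg)
        sup = truth.pattern_support("Pos", ("a=B", "b=B"))
        se = math.sqrt(0.7 * 0.3 / 5000)
        assert abs(sup - 0.7) <= 3 * se

    def test_ground_truth_counts_match_direct_recount(self):
        cfg = basic_config(planted_patterns=[
            PlantedPattern("Pos", {"y": "B"}, 0.08)])
        table, truth = generate(cfg)
        # recount from the emitted table (missing_rate 0, levels==raw here)
        for entry in truth.pattern_counts:
            want = {i.split("=")[0]: i.split("=")[1] for i in entry["items"]}
            count = sum(
                1 for rec in table.records
                if rec["Class"] == entry["class"]
                and all(rec[a] == l for a, l in want.items())
            )
            assert count == entry["count"]

    def test_missingness_expectation(self):
        m = 11  # 10 attributes + class column
        cfg = basic_config(
            n=1000, missing_rate=0.1,
            attributes=[two_level(f"a{i}", (0.5, 0.5)) for i in range(10)],
        )
        table, _ = generate(cfg)
        incomplete = sum(
            1 for rec in table.records
            if any(v == MISSING for v in rec.values())
        )
        expected = 1000 * (1 - 0.9 ** m)
        se = math.sqrt(1000 * (1 - 0.9 ** m) * 0.9 ** m)
        assert abs(incomplete - expected) <= 4 * se
        assert drop_incomplete(table).n_records == 1000 - incomplete


class TestPresets:
    def test_preset1_matches_cohort_schema(self):
        cfg = preset_dataset1_like(n=50, seed=3)
        table, _ = generate(cfg)
        assert table.attribute_names == DATASET1_SELECTION.names
        # the emitted dialect feeds the bundled scheme without modification
        clean = drop_incomplete(select_attributes(table, DATASET1_SELECTION))
        db = encode_transactions(clean, table1_spec(), "Class")
        assert db.N == clean.n_records

    def test_preset2_matches_cohort_schema(self):
        cfg = preset_dataset2_like(n=50, seed=3)
        table, _ = generate(cfg)
        assert table.attribute_names == DATASET2_SELECTION.names
        clean = drop_incomplete(select_attributes(table, DATASET2_SELECTION))
        db = encode_transactions(clean, table2_spec(), "Class")
        assert db.N == 50

    def test_preset1_raw_values_look_like_the_source_dialect(self):
        table, _ = generate(preset_dataset1_like(n=30, seed=1, missing_rate=0))
        rec = table.records[0]
        assert rec["On_thyroxine"] in {"f", "t"}
        assert rec["Class"] in {"negative", "sick"}
        assert 20 <= float(rec["Age"]) < 80
        assert float(rec["TSH"]) > 0

    def test_recovery_config_pins_marginals_to_joint(self):
        cfg = recovery_config(n_per_class=100, seed=2)
        probs = {p.probability for p in cfg.planted_patterns}
        assert probs == {0.95, 0.75, 0.55}
        for pat in cfg.planted_patterns:
            for attr in pat.items:
                spec = next(a for a in cfg.attributes if a.name == attr)
                assert spec.prob_of("Positive", "True") == pytest.approx(
                    pat.probability)

    def test_end_to_end_group_sizes(self):
        table, truth = generate(preset_dataset2_like(n=600, seed=9))
        clean = drop_incomplete(select_attributes(table, DATASET2_SELECTION))
        db = encode_transactions(clean, table2_spec(), "Class")
        groups = split_by_class(db, "Class")
        assert groups["Negative"].N == truth.class_counts["Negative"]
        assert groups["Positive"].N == truth.class_counts["Positive"]
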