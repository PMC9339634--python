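"""Synthetic transaction databases with known ground truth.

The generator emulates the statistical shape of small clinical cohorts: a
class column (disease Negative/Positive) with configurable imbalance, a
mix of boolean and discretized-numeric attributes with per-class level
probabilities, *planted patterns* — itemsets forced to co-occur within a
class at a known joint probability — and optional uniform missingness.

Planting uses a mixture, not a copula: for a pattern with joint
probability p inside class g, each record of g independently realizes the
whole pattern with probability p; otherwise its attributes are drawn from
residual marginals rescaled so the overall per-class marginals still match
the configuration (this requires p <= each pattern item's configured
marginal). Patterns in the same class must use disjoint attribute sets so
their ground-truth probabilities stay exact. Note the realized joint
probability is p plus the (usually small) chance of accidental
co-occurrence under the residual draws; it equals p exactly when at least
one pattern item's within-class marginal equals p (the residual for that
item is then zero). :class:`GroundTruth` always records realized counts by
direct recount, so tests against it are exact either way.

Rows are emitted as raw values (e.g. ``f``/``t`` booleans, numeric lab
values sampled inside or outside the reference range) so the full
ingest → discretize → mine pipeline is exercised; the ground truth is
recorded at the level (post-discretization) stage, before missingness is
injected.

Draw order is fixed — class, then per-pattern forcing masks, then
attributes in configuration order (levels, then raw rendering), then
missingness — so output is bit-stable for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .ingest import MISSING, RawTable
from .discretize import render_item


class SyntheticConfigError(Exception):
    """Invalid or infeasible generator configuration."""


#: A renderer turns a level into raw cell strings: either a constant
#: string or a callable ``(rng, size) -> sequence of str``.
Renderer = str | Callable[[np.random.Generator, int], Sequence[str]]


def uniform_int(lo: int, hi: int) -> Renderer:
    """Raw values uniform over the integers [lo, hi)."""
    def render(rng: np.random.Generator, size: int) -> list[str]:
        return [str(int(v)) for v in rng.integers(lo, hi, size=size)]
    return render


def uniform_in(lo: float, hi: float, decimals: int = 4) -> Renderer:
    """Raw numeric values uniform in [lo, hi], e.g. an in-range lab value."""
    def render(rng: np.random.Generator, size: int) -> list[str]:
        return [f"{v:.{decimals}f}" for v in rng.uniform(lo, hi, size=size)]
    return render


def outside_range(lo: float, hi: float, decimals: int = 4) -> Renderer:
    """Raw numeric values strictly outside [lo, hi] (half below, half
    above, when a below-range value is representable)."""
    below_lo, below_hi = lo * 0.1, lo * 0.9
    above_lo, above_hi = hi * 1.1, hi * 2.0

    def render(rng: np.random.Generator, size: int) -> list[str]:
        out = []
        sides = rng.random(size)
        lows = rng.uniform(below_lo, below_hi, size=size)
        highs = rng.uniform(above_lo, above_hi, size=size)
        for side, lo_v, hi_v in zip(sides, lows, highs):
            v = lo_v if (side < 0.5 and lo > 0) else hi_v
            out.append(f"{v:.{decimals}f}")
        return out
    return render


@dataclass(frozen=True)
class AttributeSpec:
    """One synthetic attribute: its levels, per-class level probabilities,
    and how each level renders to a raw cell value (default: the level
    label itself)."""

    name: str
    levels: tuple[str, ...]
    probs: Mapping[str, tuple[float, ...]]  # class level -> probs over levels
    render: Mapping[str, Renderer] = field(default_factory=dict)

    def prob_of(self, class_level: str, level: str) -> float:
        return self.probs[class_level][self.levels.index(level)]


@dataclass(frozen=True)
class PlantedPattern:
    """An itemset forced to co-occur within one class at probability p."""

    class_level: str
    items: Mapping[str, str]  # attribute -> level
    probability: float

    def rendered_items(self) -> tuple[str, ...]:
        return tuple(sorted(render_item(a, l) for a, l in self.items.items()))


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic cohort."""

    n: int
    class_levels: Mapping[str, float]            # class level -> proportion
    attributes: list[AttributeSpec]
    planted_patterns: list[PlantedPattern] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    class_attr: str = "Class"
    class_render: Mapping[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("n must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise SyntheticConfigError("missing_rate must be in [0, 1)")
        if abs(sum(self.class_levels.values()) - 1.0) > 1e-9:
            raise SyntheticConfigError("class proportions must sum to 1")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SyntheticConfigError("duplicate attribute names")
        for a in self.attributes:
            for cl in self.class_levels:
                if cl not in a.probs:
                    raise SyntheticConfigError(
                        f"attribute {a.name!r} has no probabilities for "
                        f"class {cl!r}")
                p = a.probs[cl]
                if len(p) != len(a.levels):
                    raise SyntheticConfigError(
                        f"attribute {a.name!r}: {len(p)} probabilities for "
                        f"{len(a.levels)} levels")
                if abs(sum(p) - 1.0) > 1e-9:
                    raise SyntheticConfigError(
                        f"attribute {a.name!r} class {cl!r}: probabilities "
                        f"sum to {sum(p)}")
        by_name = {a.name: a for a in self.attributes}
        claimed: dict[str, set[str]] = {cl: set() for cl in self.class_levels}
        for pat in self.planted_patterns:
            if pat.class_level not in self.class_levels:
                raise SyntheticConfigError(
                    f"pattern targets unknown class {pat.class_level!r}")
            if not 0 < pat.probability <= 1:
                raise SyntheticConfigError(
                    f"pattern probability must be in (0, 1], got "
                    f"{pat.probability}")
            overlap = claimed[pat.class_level] & set(pat.items)
            if overlap:
                raise SyntheticConfigError(
                    f"patterns overlap on {sorted(overlap)} in class "
                    f"{pat.class_level!r}")
            claimed[pat.class_level] |= set(pat.items)
            for attr, level in pat.items.items():
                if attr not in by_name:
                    raise SyntheticConfigError(
                        f"pattern uses unknown attribute {attr!r}")
                spec = by_name[attr]
                if level not in spec.levels:
                    raise SyntheticConfigError(
                        f"pattern level {level!r} not a level of {attr!r}")
                q = spec.prob_of(pat.class_level, level)
                if q < pat.probability - 1e-12:
                    raise SyntheticConfigError(
                        f"pattern {pat.rendered_items()} infeasible: "
                        f"p={pat.probability} exceeds marginal "
                        f"P({attr}={level}|{pat.class_level})={q}")


@dataclass
class GroundTruth:
    """Realized (not just expected) per-class counts, recorded before
    missingness is injected."""

    class_counts: dict[str, int]
    item_counts: dict[str, dict[str, int]]        # class -> item -> count
    pattern_counts: list[dict]                    # one entry per pattern

    def pattern_support(self, class_level: str, items: tuple[str, ...]) -> float:
        for entry in self.pattern_counts:
            if entry["class"] == class_level and tuple(entry["items"]) == items:
                return entry["count"] / self.class_counts[class_level]
        raise KeyError((class_level, items))


def _residual(probs: np.ndarray, forced_idx: int, p: float) -> np.ndarray:
    """Distribution of an attribute when its pattern was *not* forced, such
    that mixture p·δ(forced level) + (1-p)·residual equals the marginal."""
    r = probs.copy()
    r[forced_idx] = probs[forced_idx] - p
    r = r / (1.0 - p)
    if (r < -1e-12).any():
        raise SyntheticConfigError("negative residual marginal")
    return np.clip(r, 0.0, None) / np.clip(r, 0.0, None).sum()


def generate(config: SyntheticConfig) -> tuple[RawTable, GroundTruth]:
    """Draw one cohort. Reproducible: equal configs (including seed) yield
    identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    class_levels = list(config.class_levels)
    class_probs = np.array([config.class_levels[c] for c in class_levels])
    classes = rng.choice(len(class_levels), size=n, p=class_probs)
    class_col = np.array(class_levels, dtype=object)[classes]

    # per-pattern forcing masks, drawn in pattern order
    forced_masks: list[np.ndarray] = []
    for pat in config.planted_patterns:
        in_class = class_col == pat.class_level
        mask = np.zeros(n, dtype=bool)
        mask[in_class] = rng.random(int(in_class.sum())) < pat.probability
        forced_masks.append(mask)

    pattern_for_attr: dict[tuple[str, str], tuple[PlantedPattern, np.ndarray]] = {}
    for pat, mask in zip(config.planted_patterns, forced_masks):
        for attr in pat.items:
            pattern_for_attr[(pat.class_level, attr)] = (pat, mask)

    level_cols: dict[str, np.ndarray] = {}
    raw_cols: dict[str, np.ndarray] = {}
    for spec in config.attributes:
        levels = np.empty(n, dtype=object)
        for ci, cl in enumerate(class_levels):
            rows = np.flatnonzero(classes == ci)
            if rows.size == 0:
                continue
            probs = np.array(spec.probs[cl], dtype=float)
            hit = pattern_for_attr.get((cl, spec.name))
            if hit is None:
                drawn = rng.choice(len(spec.levels), size=rows.size, p=probs)
                levels[rows] = np.array(spec.levels, dtype=object)[drawn]
            else:
                pat, mask = hit
                forced_idx = spec.levels.index(pat.items[spec.name])
                forced_rows = rows[mask[rows]]
                free_rows = rows[~mask[rows]]
                levels[forced_rows] = spec.levels[forced_idx]
                if free_rows.size:
                    r = _residual(probs, forced_idx, pat.probability)
                    drawn = rng.choice(len(spec.levels), size=free_rows.size, p=r)
                    levels[free_rows] = np.array(spec.levels, dtype=object)[drawn]
        level_cols[spec.name] = levels
        # raw rendering, per level, in level order
        raw = np.empty(n, dtype=object)
        for li, level in enumerate(spec.levels):
            rows = np.flatnonzero(levels == level)
            if rows.size == 0:
                continue
            renderer = spec.render.get(level, level)
            if callable(renderer):
                raw[rows] = np.array(list(renderer(rng, rows.size)), dtype=object)
            else:
                raw[rows] = renderer
        raw_cols[spec.name] = raw

    # ground truth from the level matrix (pre-missingness)
    class_counts = {cl: int((class_col == cl).sum()) for cl in class_levels}
    item_counts: dict[str, dict[str, int]] = {cl: {} for cl in class_levels}
    for spec in config.attributes:
        for cl in class_levels:
            in_class = class_col == cl
            for level in spec.levels:
                c = int(((level_cols[spec.name] == level) & in_class).sum())
                item_counts[cl][render_item(spec.name, level)] = c
    pattern_counts = []
    for pat in config.planted_patterns:
        hit = class_col == pat.class_level
        for attr, level in pat.items.items():
            hit = hit & (level_cols[attr] == level)
        pattern_counts.append({
            "class": pat.class_level,
            "items": list(pat.rendered_items()),
            "probability": pat.probability,
            "count": int(hit.sum()),
        })
    truth = GroundTruth(class_counts, item_counts, pattern_counts)

    # raw class rendering
    class_raw = np.array(
        [config.class_render.get(cl, cl) for cl in class_col], dtype=object
    )

    columns = [spec.name for spec in config.attributes] + [config.class_attr]
    matrix = np.column_stack(
        [raw_cols[spec.name] for spec in config.attributes] + [class_raw]
    )
    if config.missing_rate > 0:
        holes = rng.random(matrix.shape) < config.missing_rate
        matrix = matrix.copy()
        matrix[holes] = MISSING
    records = [
        {col: str(matrix[i, j]) for j, col in enumerate(columns)}
        for i in range(n)
    ]
    table = RawTable(records=records, attribute_names=columns,
                     source_label=f"synthetic(seed={config.seed})")
    return table, truth


def write_csv(table: RawTable, path) -> None:
    """Emit the same CSV dialect the ingest module reads back."""
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Presets echoing the two study cohorts
# ---------------------------------------------------------------------------

def _boolean_attr(name: str, p_false: Mapping[str, float]) -> AttributeSpec:
    return AttributeSpec(
        name=name, levels=("False", "True"),
        probs={cl: (p, 1.0 - p) for cl, p in p_false.items()},
        render={"False": "f", "True": "t"},
    )


def _lab_attr(name: str, lo: float, hi: float,
              p_normal: Mapping[str, float]) -> AttributeSpec:
    return AttributeSpec(
        name=name, levels=("Normal", "Abnormal"),
        probs={cl: (p, 1.0 - p) for cl, p in p_normal.items()},
        render={"Normal": uniform_in(lo, hi), "Abnormal": outside_range(lo, hi)},
    )


def preset_dataset1_like(n: int = 2800, seed: int = 0,
                         missing_rate: float = 0.0066) -> SyntheticConfig:
    """A thyroid-cohort-shaped configuration: 20 attributes + class, ~6%
    disease-positive, boolean histories, five lab values with reference
    ranges, decade age bins, and planted patterns echoing the strongest
    within-group associations (no-I131-treatment/no-hypopituitary in the
    healthy group; female with abnormal T3 in the sick group).

    The default per-cell missing rate is calibrated so that, over 21
    columns, roughly 13% of records carry at least one hole — the
    attrition a cohort of this shape shows under complete-case cleaning.
    """
    neg, pos = "Negative", "Positive"
    age_bins = [(f"{lo}-{lo+10}", lo) for lo in range(20, 80, 10)]
    attrs = [
        AttributeSpec(
            name="Age",
            levels=tuple(label for label, _ in age_bins),
            probs={neg: (0.18, 0.22, 0.20, 0.16, 0.14, 0.10),
                   pos: (0.10, 0.14, 0.18, 0.22, 0.20, 0.16)},
            render={label: uniform_int(lo, lo + 10) for label, lo in age_bins},
        ),
        AttributeSpec(
            name="Sex", levels=("F", "M"),
            probs={neg: (0.66, 0.34), pos: (0.85, 0.15)},
        ),
        _boolean_attr("On_thyroxine", {neg: 0.86, pos: 0.90}),
        _boolean_attr("On_antithyroid_med", {neg: 0.99, pos: 0.98}),
        _boolean_attr("Sick", {neg: 0.97, pos: 0.90}),
        _boolean_attr("Pregnant", {neg: 0.99, pos: 0.99}),
        _boolean_attr("Thyroid_surgery", {neg: 0.98, pos: 0.72}),
        _boolean_attr("I131", {neg: 0.99, pos: 0.95}),
        _boolean_attr("Query_hypothyroid", {neg: 0.97, pos: 0.95}),
        _boolean_attr("Query_hyperthyroid", {neg: 0.94, pos: 0.96}),
        _boolean_attr("Lithium", {neg: 0.995, pos: 0.99}),
        _boolean_attr("Goiter", {neg: 0.99, pos: 0.98}),
        _boolean_attr("Tumor", {neg: 0.97, pos: 0.95}),
        _boolean_attr("Hypopituitary", {neg: 0.995, pos: 0.999}),
        _boolean_attr("Psych", {neg: 0.95, pos: 0.97}),
        _lab_attr("TSH", 0.27, 4.2, {neg: 0.85, pos: 0.75}),
        _lab_attr("T3", 1.3, 3.1, {neg: 0.90, pos: 0.12}),
        _lab_attr("TT4", 62, 164, {neg: 0.92, pos: 0.70}),
        _lab_attr("T4U", 0.7, 1.8, {neg: 0.94, pos: 0.85}),
        _lab_attr("FTI", 53, 142, {neg: 0.93, pos: 0.80}),
    ]
    patterns = [
        PlantedPattern(neg, {"I131": "False", "Hypopituitary": "False"}, 0.98),
        PlantedPattern(pos, {"Sex": "F", "T3": "Abnormal"}, 0.80),
    ]
    return SyntheticConfig(
        n=n, class_levels={neg: 0.94, pos: 0.06}, attributes=attrs,
        planted_patterns=patterns, missing_rate=missing_rate, seed=seed,
        class_attr="Class",
        class_render={neg: "negative", pos: "sick"},
    )


def preset_dataset2_like(n: int = 303, seed: int = 0,
                         missing_rate: float = 0.0) -> SyntheticConfig:
    """A cardiology-registry-shaped configuration: 14 attributes + class,
    ~5% thyroid-disease-positive, comorbidity booleans, age split at 50,
    planted patterns echoing the strongest associations (no chronic renal
    failure/no stroke in the healthy group; hypertension and obesity in
    the sick group)."""
    neg, pos = "Negative", "Positive"
    attrs = [
        AttributeSpec(
            name="Age", levels=("≤50", ">50"),
            probs={neg: (0.24, 0.76), pos: (0.20, 0.80)},
            render={"≤50": uniform_int(25, 51), ">50": uniform_int(51, 87)},
        ),
        AttributeSpec(
            name="Gender", levels=("F", "M"),
            probs={neg: (0.42, 0.58), pos: (0.72, 0.28)},
            render={"F": "Fmale", "M": "Male"},
        ),
        AttributeSpec(
            name="Diabetes_mellitus", levels=("False", "True"),
            probs={neg: (0.70, 0.30), pos: (0.62, 0.38)},
            render={"False": "0", "True": "1"},
        ),
        AttributeSpec(
            name="Hypertension", levels=("False", "True"),
            probs={neg: (0.42, 0.58), pos: (0.29, 0.71)},
            render={"False": "0", "True": "1"},
        ),
        AttributeSpec(
            name="Current_smoker", levels=("False", "True"),
            probs={neg: (0.79, 0.21), pos: (0.90, 0.10)},
            render={"False": "0", "True": "1"},
        ),
        AttributeSpec(
            name="Ex_smoker", levels=("False", "True"),
            probs={neg: (0.96, 0.04), pos: (0.97, 0.03)},
            render={"False": "0", "True": "1"},
        ),
        AttributeSpec(
            name="Obesity", levels=("False", "True"),
            probs={neg: (0.32, 0.68), pos: (0.29, 0.71)},
            render={"False": "N", "True": "Y"},
        ),
        _boolean_attr("CRF", {neg: 0.995, pos: 1.0}),
        _boolean_attr("CVA", {neg: 0.98, pos: 0.99}),
        _boolean_attr("AD", {neg: 0.97, pos: 0.96}),
        AttributeSpec(
            name="Edema", levels=("False", "True"),
            probs={neg: (0.96, 0.04), pos: (0.93, 0.07)},
            render={"False": "0", "True": "1"},
        ),
        _boolean_attr("LR", {neg: 0.96, pos: 0.95}),
        _boolean_attr("Dyspnea", {neg: 0.56, pos: 0.55}),
        AttributeSpec(
            name="CAD", levels=("False", "True"),
            probs={neg: (0.30, 0.70), pos: (0.35, 0.65)},
            render={"False": "Normal", "True": "Cad"},
        ),
    ]
    patterns = [
        PlantedPattern(neg, {"CRF": "False", "CVA": "False"}, 0.97),
        PlantedPattern(pos, {"Hypertension": "True"}, 0.71),
        PlantedPattern(pos, {"Obesity": "True"}, 0.71),
    ]
    return SyntheticConfig(
        n=n, class_levels={neg: 0.95, pos: 0.05}, attributes=attrs,
        planted_patterns=patterns, missing_rate=missing_rate, seed=seed,
        class_attr="Class",
        class_render={neg: "N", pos: "Y"},
    )


def recovery_config(n_per_class: int = 5000, seed: int = 0) -> SyntheticConfig:
    """Two balanced classes with three patterns planted in the positive
    class at joint probabilities 0.95, 0.75 and 0.55 on disjoint attribute
    pairs — the configuration used to check that mining at threshold 0.6
    recovers exactly the patterns whose probability clears it.

    Each pattern item's within-class marginal equals the pattern's joint
    probability, so the residual draws contribute no accidental
    co-occurrence and the planted probability is realized exactly (up to
    binomial sampling)."""
    neg, pos = "Negative", "Positive"

    def pair(i: int, p: float) -> list[AttributeSpec]:
        return [
            _boolean_attr(f"RiskA{i}", {neg: 0.5, pos: 1.0 - p}),
            _boolean_attr(f"RiskB{i}", {neg: 0.5, pos: 1.0 - p}),
        ]

    attrs = pair(1, 0.95) + pair(2, 0.75) + pair(3, 0.55) + [
        _boolean_attr("Background", {neg: 0.5, pos: 0.5}),
    ]
    patterns = [
        PlantedPattern(pos, {"RiskA1": "True", "RiskB1": "True"}, 0.95),
        PlantedPattern(pos, {"RiskA2": "True", "RiskB2": "True"}, 0.75),
        PlantedPattern(pos, {"RiskA3": "True", "RiskB3": "True"}, 0.55),
    ]
    return SyntheticConfig(
        n=2 * n_per_class, class_levels={neg: 0.5, pos: 0.5},
        attributes=attrs, planted_patterns=patterns,
        missing_rate=0.0, seed=seed,
    )
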