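"""End-to-end orchestration: ingest → select → clean → discretize →
stratify → mine with both algorithms → class rules → consensus → report.

Both miners always run and their rule sets are intersected; the consensus
stage is the pipeline's integrity mechanism (exact miners must agree, so a
non-empty exclusive set flags a bug, never a result). Record counts are
logged after every stage. Artifacts are written atomically: everything is
rendered in memory, written to a temporary directory next to the target,
and moved into place only when complete.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import ingest
from .ingest import AttributeSelection, RawTable
from .discretize import (
    Bins, BinaryThreshold, Categorical, DiscretizationSpec, NormalRange,
    PRESET_SPECS, Rule, TransactionDB, boolean_rule, encode_transactions,
    render_item, split_by_class,
)
from .apriori import apriori_mine
from .fpgrowth import fpgrowth_mine
from .rules import RuleSet, Thresholds, generate_class_rules
from .consensus import ConsensusReport, mutual_rules

logger = logging.getLogger("thyromine")


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


_DATASET_PRESETS = {
    "dataset1": (ingest.DATASET1_SELECTION, "dataset1"),
    "dataset2": (ingest.DATASET2_SELECTION, "dataset2"),
}


def _rule_from_dict(attr: str, d: Mapping) -> Rule:
    kind = d.get("kind")
    if kind == "categorical":
        levels = tuple(d["levels"]) if "levels" in d else None
        return Categorical(mapping=d.get("mapping"), levels=levels)
    if kind == "boolean":
        return boolean_rule()
    if kind == "normal_range":
        return NormalRange(float(d["lo"]), float(d["hi"]))
    if kind == "bins":
        return Bins(tuple((str(b[0]), float(b[1]), float(b[2]))
                          for b in d["bins"]))
    if kind == "binary_threshold":
        return BinaryThreshold(float(d["cut"]), d.get("le_label"),
                               d.get("gt_label"))
    raise PipelineError(f"unknown discretization kind {kind!r} for {attr!r}")


@dataclass
class RunConfig:
    """One mining run, fully specified.

    Either ``dataset_preset`` names a bundled scheme (selection +
    discretization) or ``selection``/``discretization`` supply them
    inline.
    """

    input_path: str
    dialect: str = "csv"
    dataset_preset: str | None = None
    selection: AttributeSelection | None = None
    discretization: DiscretizationSpec | None = None
    class_attr: str = "Class"
    thresholds: Thresholds = field(default_factory=Thresholds)
    # Cap on antecedent size. Clinical cohorts put most records at the
    # reference level of most attributes, so nearly-universal items make
    # the unlimited frequent set combinatorially huge (hundreds of
    # thousands of itemsets at support 0.6); reported rule depth is 3.
    # None = unlimited.
    max_antecedent: int | None = 3
    output_dir: str | None = None
    age_filter: bool = False
    on_out_of_bin: str = "raise"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.dataset_preset is not None:
            if self.dataset_preset not in _DATASET_PRESETS:
                raise PipelineError(
                    f"unknown dataset preset {self.dataset_preset!r}; "
                    f"known: {sorted(_DATASET_PRESETS)}")
            sel, spec_name = _DATASET_PRESETS[self.dataset_preset]
            self.selection = sel
            self.discretization = PRESET_SPECS[spec_name](self.on_out_of_bin)
        if self.selection is None or self.discretization is None:
            raise PipelineError(
                "either dataset_preset or both selection and discretization "
                "must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        if "input_path" not in raw:
            raise PipelineError("config missing required key: input_path")
        selection = None
        if "selection" in raw:
            s = raw["selection"]
            selection = AttributeSelection(
                names=list(s["names"]), rename_map=dict(s.get("rename_map", {}))
            )
        discretization = None
        if "discretization" in raw:
            d = raw["discretization"]
            discretization = DiscretizationSpec(
                rules={a: _rule_from_dict(a, r) for a, r in d.items()},
                on_out_of_bin=raw.get("on_out_of_bin", "raise"),
            )
        th = raw.get("thresholds", {})
        return cls(
            input_path=str(raw["input_path"]),
            dialect=raw.get("dialect", "csv"),
            dataset_preset=raw.get("dataset_preset"),
            selection=selection,
            discretization=discretization,
            class_attr=raw.get("class_attr", "Class"),
            thresholds=Thresholds(
                min_support=th.get("min_support", 0.6),
                min_confidence=th.get("min_confidence", 0.9),
            ),
            max_antecedent=raw.get("max_antecedent", 3),
            output_dir=raw.get("output_dir"),
            age_filter=bool(raw.get("age_filter", False)),
            on_out_of_bin=raw.get("on_out_of_bin", "raise"),
            log_level=raw.get("log_level", "INFO"),
        )


@dataclass
class RunArtifacts:
    """Everything one run produces, in memory."""

    stage_log: list[str]
    group_sizes: dict[str, int]
    rule_sets: dict[tuple[str, str], RuleSet]        # (group, algorithm)
    consensus: dict[str, ConsensusReport]            # group -> report

    def mutual(self, group: str) -> RuleSet:
        return self.consensus[group].mutual


def run(config: RunConfig, raw: RawTable | None = None) -> RunArtifacts:
    """Execute the full pipeline; ``raw`` bypasses the read stage (used by
    the simulate path, which already holds the generated table)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    log: list[str] = []

    def stage(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    try:
        if raw is None:
            if config.dataset_preset == "dataset1" and config.dialect == "uci_data":
                raw = ingest.read_sick_data(config.input_path)
            else:
                raw = ingest.read_table(config.input_path, config.dialect)
        stage(f"read: {raw.n_records} records, "
              f"{len(raw.attribute_names)} attributes")
    except ingest.IngestError as exc:
        raise PipelineError(f"read stage: {exc}") from exc

    try:
        assert config.selection is not None
        selected = ingest.select_attributes(raw, config.selection)
        stage(f"select: {len(selected.attribute_names)} attributes retained")
        clean = ingest.drop_incomplete(selected)
        stage(f"clean: {selected.n_records} -> {clean.n_records} records "
              f"(removed {selected.n_records - clean.n_records} incomplete)")
        if config.age_filter:
            before = clean.n_records
            clean = ingest.clean_dataset1(raw, age_filter=True) \
                if config.dataset_preset == "dataset1" else clean
            stage(f"age filter: {before} -> {clean.n_records} records")
    except ingest.IngestError as exc:
        raise PipelineError(f"selection/cleaning stage: {exc}") from exc

    try:
        assert config.discretization is not None
        db = encode_transactions(clean, config.discretization, config.class_attr)
        if db.N < clean.n_records:
            stage(f"discretize: dropped {clean.n_records - db.N} "
                  f"out-of-bin records")
        stage(f"discretize: {db.N} transactions, "
              f"{len(db.item_universe)} distinct items")
        groups = split_by_class(db, config.class_attr)
        for level in sorted(groups):
            stage(f"group {level}: {groups[level].N} transactions")
    except Exception as exc:
        raise PipelineError(f"discretization stage: {exc}") from exc

    rule_sets: dict[tuple[str, str], RuleSet] = {}
    consensus: dict[str, ConsensusReport] = {}
    dataset_label = config.dataset_preset or Path(config.input_path).name
    for level in sorted(groups):
        gdb = groups[level]
        if gdb.N == 0:
            continue
        class_item = render_item(config.class_attr, level)
        try:
            for name, miner in (("apriori", apriori_mine),
                                ("fpgrowth", fpgrowth_mine)):
                frequent = miner(gdb, config.thresholds.min_support,
                                 max_len=None if config.max_antecedent is None
                                 else config.max_antecedent)
                rs = generate_class_rules(
                    gdb, class_item, frequent, config.thresholds,
                    max_antecedent=config.max_antecedent,
                    provenance={"algorithm": name, "dataset": dataset_label,
                                "group": level},
                )
                rule_sets[(level, name)] = rs
                stage(f"mine[{name}] group {level}: {len(rs)} rules")
            report = mutual_rules(rule_sets[(level, "apriori")],
                                  rule_sets[(level, "fpgrowth")])
            consensus[level] = report
            stage(f"consensus group {level}: {len(report.mutual)} mutual, "
                  f"{len(report.only_first)}/{len(report.only_second)} "
                  f"exclusive")
        except Exception as exc:
            raise PipelineError(f"mining stage (group {level}): {exc}") from exc

    artifacts = RunArtifacts(
        stage_log=log,
        group_sizes={lvl: g.N for lvl, g in groups.items()},
        rule_sets=rule_sets,
        consensus=consensus,
    )
    if config.output_dir is not None:
        write_artifacts(artifacts, config.output_dir)
    return artifacts


def write_artifacts(artifacts: RunArtifacts, output_dir: str | Path) -> None:
    """Render all artifacts and move them into ``output_dir`` atomically."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {"stage_log.txt": "\n".join(artifacts.stage_log) + "\n"}
    for (group, algo), rs in artifacts.rule_sets.items():
        files[f"rules_{group}_{algo}.csv"] = rs.to_csv()
        files[f"rules_{group}_{algo}.json"] = rs.to_json()
    for group, report in artifacts.consensus.items():
        files[f"consensus_{group}.csv"] = report.to_csv()
        files[f"consensus_{group}.json"] = report.to_json()
    tmp = Path(tempfile.mkdtemp(dir=output_dir, prefix=".tmp-"))
    try:
        for name, content in files.items():
            (tmp / name).write_text(content, encoding="utf-8")
        for name in files:
            os.replace(tmp / name, output_dir / name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
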