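"""End-to-end orchestration: simulate → apply methods → evaluate.

A run is specified by a :class:`RunConfig` (simulation parameters, a list
of method specs, an output directory and one master seed).  All outputs
are flat TSVs plus one JSON manifest with file checksums; identical
config and seed give byte-identical outputs.  Per-method random streams
are derived from the master seed keyed by method label and sample, so
adding a method never perturbs the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_data import (
    AsvTable,
    ExpectedReference,
    SampleMetadata,
    ValidationError,
    metadata_by_id,
    write_asv_table,
    write_metadata,
    write_reference,
)
from .evaluation import (
    ALPHA_METRICS,
    alpha_diversity_table,
    composition_recovery,
    confusion_and_accuracy,
    dataset_confusion,
    expected_alpha,
    label_ground_truth,
    sample_summary,
)
from .removal_methods import (
    RemovalResult,
    decontam_classify,
    decontam_frequency_scores,
    filter_by_abundance,
    filter_by_negative_control,
)
from .sourcetracker import build_source_set, gibbs_source_attribution, sourcetracker_correct
from .synthetic_data import (
    SimulatedExperiment,
    SimulationConfig,
    derive_seed,
    mock_profile_of,
    simulate_dilution_series,
    write_ground_truth,
)

logger = logging.getLogger("contambench")

SCENARIO_NAMES = {
    1: "defined_experimental_source",
    2: "undefined_experimental_source",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class MethodSpec:
    """One method × parameter combination of the evaluation grid."""

    name: str  # negctrl | abundance | frequency | sourcetracker
    params: Mapping[str, object] = field(default_factory=dict)

    def label(self) -> str:
        if self.name == "negctrl":
            return "negctrl"
        if self.name == "abundance":
            return f"abundance_{self.params['threshold']:g}"
        if self.name == "frequency":
            return f"frequency_{self.params['p_star']:g}"
        if self.name == "sourcetracker":
            return (
                f"sourcetracker_s{self.params['scenario']}_case{self.params['case']}"
            )
        raise ValidationError(f"unknown method {self.name!r}")

    @classmethod
    def parse(cls, text: str) -> "MethodSpec":
        """Parse a compact spec string: ``negctrl``, ``abundance:0.001``
        (proportion), ``frequency:0.3``, ``sourcetracker:s1c2``."""
        name, _, arg = text.partition(":")
        if name == "negctrl":
            return cls("negctrl")
        if name == "abundance":
            return cls("abundance", {"threshold": float(arg)})
        if name == "frequency":
            return cls("frequency", {"p_star": float(arg)})
        if name == "sourcetracker":
            arg = arg.lower()
            if len(arg) == 4 and arg[0] == "s" and arg[2] == "c":
                return cls(
                    "sourcetracker", {"scenario": int(arg[1]), "case": int(arg[3])}
                )
            raise ValidationError(
                f"sourcetracker spec must look like 'sourcetracker:s1c2', got {text!r}"
            )
        raise ValidationError(f"unknown method spec {text!r}")


def default_method_grid() -> list[MethodSpec]:
    """The full evaluation grid: one negative-control filter, abundance
    thresholds 0.01/0.1/1 %, frequency thresholds P* 0.1–0.5, and the
    four source-tracking scenario × case combinations."""
    grid: list[MethodSpec] = [MethodSpec("negctrl")]
    grid += [
        MethodSpec("abundance", {"threshold": t}) for t in (0.0001, 0.001, 0.01)
    ]
    grid += [
        MethodSpec("frequency", {"p_star": p}) for p in (0.1, 0.2, 0.3, 0.4, 0.5)
    ]
    grid += [
        MethodSpec("sourcetracker", {"scenario": s, "case": c})
        for s in (1, 2)
        for c in (1, 2)
    ]
    return grid


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    methods: list[MethodSpec] = field(default_factory=default_method_grid)
    output_dir: Path = Path("results/run")
    seed: int = 0
    log_level: str = "WARNING"
    sourcetracker_hyperparams: dict[str, float | int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spec in self.methods:
            spec.label()  # validates method names/params early


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    files: dict[str, str]
    created_utc: str
    wall_seconds: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _config_snapshot(config: RunConfig) -> dict:
    sim = dataclasses.asdict(config.simulation)
    sim["reads_per_sample"] = (
        list(sim["reads_per_sample"])
        if isinstance(sim["reads_per_sample"], tuple)
        else sim["reads_per_sample"]
    )
    return {
        "simulation": sim,
        "methods": [
            {"name": m.name, "params": dict(m.params)} for m in config.methods
        ],
        "seed": config.seed,
        "log_level": config.log_level,
        "sourcetracker_hyperparams": dict(config.sourcetracker_hyperparams),
    }


# ---------------------------------------------------------------------------
# Method dispatch
# ---------------------------------------------------------------------------

def apply_method(
    table: AsvTable,
    metadata: Sequence[SampleMetadata],
    reference: ExpectedReference,
    spec: MethodSpec,
    seed: int = 0,
    sourcetracker_hyperparams: Mapping[str, float | int] | None = None,
) -> RemovalResult:
    """Run one method on a table (controls identified from metadata)."""
    meta = metadata_by_id(metadata)
    control_ids = [s for s in table.sample_ids if meta[s].is_control]
    sink_ids = [s for s in table.sample_ids if not meta[s].is_control]
    if spec.name == "negctrl":
        return filter_by_negative_control(table, control_ids)
    if spec.name == "abundance":
        sinks = table.subset_samples(sink_ids)
        return filter_by_abundance(sinks, float(spec.params["threshold"]))
    if spec.name == "frequency":
        fit = decontam_frequency_scores(table, metadata)
        return decontam_classify(fit, float(spec.params["p_star"]))
    if spec.name == "sourcetracker":
        scenario = SCENARIO_NAMES[int(spec.params["scenario"])]
        case = int(spec.params["case"])
        mock_sample = _undiluted_sample_id(metadata)
        sources = build_source_set(
            table,
            reference,
            control_ids,
            scenario,
            case,
            mock_sample_id=mock_sample,
        )
        label = spec.label()
        attributions = {}
        for s in sink_ids:
            logger.info("gibbs attribution: %s / sample %s", label, s)
            attributions[s] = gibbs_source_attribution(
                table.column(s),
                sources,
                hyperparams=dict(sourcetracker_hyperparams or {}),
                rng=derive_seed(seed, "method", label, s),
                sink_id=s,
            )
        return sourcetracker_correct(
            table,
            attributions,
            scenario,
            experimental_source_name="mock" if scenario == SCENARIO_NAMES[1] else None,
        )
    raise ValidationError(f"unknown method {spec.name!r}")


def _undiluted_sample_id(metadata: Sequence[SampleMetadata]) -> str | None:
    for m in metadata:
        if m.dilution_round == 0:
            return m.sample_id
    return None


# ---------------------------------------------------------------------------
# Calls round-trip (the TSV contract between apply and evaluate)
# ---------------------------------------------------------------------------

def write_calls(result: RemovalResult, table: AsvTable, path: Path) -> None:
    frame = result.to_calls_frame(table)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_calls(path: Path, method_name: str | None = None) -> RemovalResult:
    frame = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "sample_id": str})
    retained = frame.pivot(
        index="asv_id", columns="sample_id", values="retained_fraction"
    )
    kept = frame.pivot(index="asv_id", columns="sample_id", values="call") == "kept"
    score = None
    if "score" in frame.columns and frame["score"].notna().any():
        score = frame.drop_duplicates("asv_id").set_index("asv_id")["score"]
    return RemovalResult(
        method_name=method_name or Path(path).stem.removeprefix("calls_"),
        params={},
        retained_fraction=retained,
        kept=kept,
        score=score,
    )


# ---------------------------------------------------------------------------
# Evaluation over a set of results
# ---------------------------------------------------------------------------

def evaluate_results(
    table: AsvTable,
    metadata: Sequence[SampleMetadata],
    reference: ExpectedReference,
    results: Mapping[str, RemovalResult],
    truth_profile: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Score every method: confusion (per-sample and dataset-wide),
    alpha diversity of corrected tables, and composition recovery.

    Without an explicit truth profile, the expected composition is taken
    from the undiluted sample restricted to the expected ASVs.
    """
    labels = label_ground_truth(table, reference)
    meta = metadata_by_id(metadata)
    sink_ids = [s for s in table.sample_ids if not meta[s].is_control]
    sinks = table.subset_samples(sink_ids)

    if truth_profile is None:
        mock_sample = _undiluted_sample_id(metadata) or sink_ids[0]
        expected_counts = table.frame.loc[
            table.frame.index.isin(reference.id_set), mock_sample
        ]
        if expected_counts.sum() == 0:
            raise ValidationError(
                "cannot derive a truth profile: undiluted sample has no "
                "expected-ASV reads"
            )
        truth_profile = expected_counts / expected_counts.sum()

    summary = sample_summary(table, labels)

    confusion_rows = []
    dataset_rows = []
    diversity_rows = []
    recovery_rows = []

    # uncorrected and expected baselines
    base_alpha = alpha_diversity_table(sinks)
    for metric in ALPHA_METRICS:
        expected = expected_alpha(sinks, reference, metric)
        for s in sink_ids:
            diversity_rows.append(
                {
                    "method": "uncorrected",
                    "sample_id": s,
                    "metric": metric,
                    "value": base_alpha.loc[s, metric],
                    "expected": expected[s],
                }
            )

    for label_name, result in results.items():
        confusion = confusion_and_accuracy(result, labels, table)
        confusion.insert(0, "method", label_name)
        confusion_rows.append(confusion.reset_index())
        ds = dataset_confusion(result, labels, table)
        dataset_rows.append({"method": label_name, **ds.to_dict()})

        corrected = result.corrected_table(table)
        corr_alpha = alpha_diversity_table(corrected)
        for metric in ALPHA_METRICS:
            expected = expected_alpha(sinks, reference, metric)
            for s in corrected.sample_ids:
                diversity_rows.append(
                    {
                        "method": label_name,
                        "sample_id": s,
                        "metric": metric,
                        "value": corr_alpha.loc[s, metric],
                        "expected": expected.get(s, np.nan),
                    }
                )
        nonzero = [s for s in corrected.sample_ids if corrected.frame[s].sum() > 0]
        if nonzero:
            recovery = composition_recovery(
                corrected.subset_samples(nonzero), truth_profile, labels
            )
            recovery.insert(0, "method", label_name)
            recovery_rows.append(recovery.reset_index())

    return {
        "summary": summary.reset_index(names="sample_id"),
        "confusion": (
            pd.concat(confusion_rows, ignore_index=True)
            if confusion_rows
            else pd.DataFrame()
        ),
        "confusion_dataset": pd.DataFrame(dataset_rows),
        "diversity": pd.DataFrame(diversity_rows),
        "recovery": (
            pd.concat(recovery_rows, ignore_index=True)
            if recovery_rows
            else pd.DataFrame()
        ),
    }


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Execute the whole study: simulate, apply every method of the grid,
    evaluate, and write a manifest.  Any stage failure raises
    :class:`StageError` naming the stage; prior outputs are left intact.
    """
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    stage = "simulate"
    try:
        sim_config = config.simulation.replace(seed=config.seed)
        experiment = simulate_dilution_series(sim_config)
        logger.info("simulated %s", experiment.table)
        write_asv_table(experiment.table, out / "table.tsv")
        write_metadata(experiment.metadata, out / "metadata.tsv")
        write_reference(experiment.reference, out / "reference.txt")
        write_ground_truth(experiment.truth, out / "ground_truth.tsv")
        files += [
            out / "table.tsv",
            out / "metadata.tsv",
            out / "reference.txt",
            out / "ground_truth.tsv",
        ]

        stage = "apply"
        results: dict[str, RemovalResult] = {}
        for spec in config.methods:
            label = spec.label()
            logger.info("applying method %s", label)
            result = apply_method(
                experiment.table,
                experiment.metadata,
                experiment.reference,
                spec,
                seed=config.seed,
                sourcetracker_hyperparams=config.sourcetracker_hyperparams,
            )
            results[label] = result
            calls_path = out / f"calls_{label}.tsv"
            write_calls(result, experiment.table, calls_path)
            files.append(calls_path)

        stage = "evaluate"
        reports = evaluate_results(
            experiment.table,
            experiment.metadata,
            experiment.reference,
            results,
            truth_profile=mock_profile_of(sim_config),
        )
        for name, frame in reports.items():
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            files.append(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config=_config_snapshot(config),
        files={str(p.relative_to(out)): _sha256(p) for p in files},
        created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        wall_seconds=round(time.monotonic() - t0, 3),
    )
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Flat config files
# ---------------------------------------------------------------------------

_RUN_KEYS = {"seed", "output_dir", "log_level", "methods", "paper_scale"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_run_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML) config: simulation fields at top level
    alongside ``seed``, ``output_dir``, ``log_level``, ``paper_scale``
    and ``methods`` (a list of compact method specs).  Unknown keys are
    an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a flat mapping")
    unknown = set(raw) - _RUN_KEYS - _SIM_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    sim_kwargs = {k: raw[k] for k in raw if k in _SIM_KEYS}
    if "reads_per_sample" in sim_kwargs and isinstance(
        sim_kwargs["reads_per_sample"], list
    ):
        sim_kwargs["reads_per_sample"] = tuple(sim_kwargs["reads_per_sample"])
    if raw.get("paper_scale"):
        simulation = SimulationConfig.paper_scale(**sim_kwargs)
    else:
        simulation = SimulationConfig(**sim_kwargs)
    methods = (
        [MethodSpec.parse(m) for m in raw["methods"]]
        if "methods" in raw
        else default_method_grid()
    )
    return RunConfig(
        simulation=simulation,
        methods=methods,
        output_dir=Path(raw.get("output_dir", "results/run")),
        seed=int(raw.get("seed", simulation.seed)),
        log_level=str(raw.get("log_level", "WARNING")),
    )
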