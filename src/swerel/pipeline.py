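"""End-to-end study replication: training, view selection, validation, ICU.

``run_study`` executes the four analysis stages of a two-operator
elastography reliability study in order:

1. **training** — per muscle and probe view, inter-operator ICC with
   operator means/SDs and a normality-gated comparison (six rows for
   the full three-muscle, two-view design);
2. **view selection** — the view with the better inter-operator ICC per
   muscle, ties resolved toward longitudinal;
3. **validation** — on the selected views, inter-operator ICC, both
   operators' intra-rater (one-way, across replicates) ICCs and
   Bland-Altman agreement;
4. **icu** — the same plus the bootstrap probability that the
   inter-operator ICC exceeds a threshold (default 0.8).

Each cohort comes either from a synthetic ``CohortSpec`` or from a user
CSV.  All randomness flows from the config's global seed through named
substreams (one per cohort plus one for the bootstrap), so a fully
synthetic run is bit-reproducible.  Every gate decision (normality
outcome, chosen test, tie-breaks, dropped cells) is logged, since
published reliability tables only show final numbers.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, compare_operators
from .design import bootstrap_icc_probability, select_best_view
from .icc import IccResult, icc_oneway, icc_twoway_agreement, icc_twoway_consistency
from .records import (
    MeasurementTable,
    count_measurements,
    operator_matrix,
    read_measurements,
    replicate_matrix,
)
from .simulate import CohortSpec, VarianceComponents, generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; completed stages are preserved."""

    def __init__(self, stage: str, message: str, report: "StudyReport"):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.report = report


@dataclass
class StudyConfig:
    """Inputs and analysis options for one full study run.

    Each cohort is either a :class:`CohortSpec` (synthetic) or a path to
    a long-format CSV.  ``icc_mode`` selects whether the inter-operator
    ICC is computed on per-operator triplicate means (``means``, the
    default) or on the full replicate-level crossed ANOVA
    (``replicates``, balanced designs only).  ``view_overrides`` forces
    a view choice for specific muscles regardless of the training
    comparison.
    """

    seed: int = 0
    training: CohortSpec | str | Path | None = None
    validation: CohortSpec | str | Path | None = None
    icu: CohortSpec | str | Path | None = None
    icc_mode: str = "means"
    icc_variant: str = "agreement"
    alpha: float = 0.05
    bootstrap_threshold: float = 0.8
    n_boot: int = 10_000
    tie_policy: str = "prefer_longitudinal"
    view_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.icc_mode not in ("means", "replicates"):
            raise ValueError("icc_mode must be 'means' or 'replicates'")
        if self.icc_variant not in ("agreement", "consistency"):
            raise ValueError("icc_variant must be 'agreement' or 'consistency'")


@dataclass
class StudyReport:
    """Structured study output; all fields are JSON-serialisable."""

    training: list = field(default_factory=list)
    selected_views: dict = field(default_factory=dict)
    validation: list = field(default_factory=list)
    icu: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyReport":
        return cls(**payload)


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Named substream seeds below 2^31 derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def default_study_config(seed: int = 0) -> StudyConfig:
    """The default synthetic study: 16 + 15 healthy subjects and 12 ICU
    patients, calibrated so each stage shows the qualitative pattern of
    a real two-operator stiffness-reliability study (one clearly better
    view per muscle in training, excellent reliability in validation
    and ICU, a few percent of uninterpretable acquisitions outside the
    training set)."""
    s_train, s_val, s_icu = _derived_seeds(seed, 3)
    fi = VarianceComponents.from_icc
    training_components = {
        ("diaphragm", "longitudinal"): fi(19.7, 40.0, 0.83),
        ("diaphragm", "transverse"): fi(24.0, 45.0, 0.30),
        ("biceps_brachii", "longitudinal"): fi(28.4, 50.0, 0.88),
        ("biceps_brachii", "transverse"): fi(13.5, 20.0, 0.39),
        ("rectus_femoris", "longitudinal"): fi(15.2, 26.0, 0.76),
        ("rectus_femoris", "transverse"): fi(23.8, 55.0, 0.82),
    }
    validation_components = {}
    for muscle, (mean, var, icc) in {
        "diaphragm": (20.3, 45.0, 0.96),
        "biceps_brachii": (23.7, 30.0, 0.91),
        "rectus_femoris": (11.5, 5.3, 0.97),
    }.items():
        for view in ("longitudinal", "transverse"):
            validation_components[(muscle, view)] = fi(mean, var, icc)
    return StudyConfig(
        seed=seed,
        training=CohortSpec(
            cohort="training",
            n_subjects=16,
            missing_rate=0.0,
            components=training_components,
            seed=s_train,
        ),
        validation=CohortSpec(
            cohort="validation",
            n_subjects=15,
            missing_rate=0.03,
            components=validation_components,
            seed=s_val,
        ),
        icu=CohortSpec(cohort="icu", n_subjects=12, missing_rate=0.03, seed=s_icu),
    )


def _load_cohort(source) -> MeasurementTable:
    if isinstance(source, CohortSpec):
        return generate_cohort(source)
    return read_measurements(source)


def _icc_result_dict(res: IccResult) -> dict:
    return {
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "band": res.band,
        "model": res.model,
        "alpha": res.alpha,
    }


def _inter_operator_icc(table: MeasurementTable, muscle: str, view: str, config: StudyConfig) -> IccResult:
    if config.icc_variant == "consistency":
        _, mat = operator_matrix(table, muscle, view, level="means")
        return icc_twoway_consistency(mat, alpha=config.alpha)
    level = "means" if config.icc_mode == "means" else "replicates"
    _, data = operator_matrix(table, muscle, view, level=level)
    return icc_twoway_agreement(data, alpha=config.alpha)


def _slice_summary(table: MeasurementTable, muscle: str, view: str) -> dict:
    frame = table.frame
    sub = frame[(frame["muscle"] == muscle) & (frame["view"] == view)]
    sliced = MeasurementTable(sub.reset_index(drop=True), provenance=table.provenance)
    op_stats = {}
    for op in (1, 2):
        means = (
            sub[sub["operator"] == op]
            .groupby("subject_id", observed=True)["shear_modulus_kpa"]
            .mean()
        )
        op_stats[f"operator{op}_mean_kpa"] = float(means.mean())
        op_stats[f"operator{op}_sd_kpa"] = float(means.std(ddof=1))
    return {
        "muscle": muscle,
        "view": view,
        "n_replicate_level": count_measurements(sliced, "replicate"),
        "n_aggregated": count_measurements(sliced, "aggregated"),
        **op_stats,
    }


def _comparison_dict(table: MeasurementTable, muscle: str, view: str, config: StudyConfig) -> dict:
    _, mat = operator_matrix(table, muscle, view, level="means")
    cmp = compare_operators(mat[:, 0], mat[:, 1], alpha_normality=config.alpha)
    logger.info(
        "%s/%s: normality p=%.3f -> %s (p=%.3f)",
        muscle,
        view,
        cmp.normality_p,
        cmp.test_name,
        cmp.p_value,
    )
    return {
        "test_name": cmp.test_name,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "normality_p": cmp.normality_p,
    }


def _reliability_row(
    table: MeasurementTable, muscle: str, view: str, config: StudyConfig
) -> tuple[dict, np.ndarray]:
    """Full per-muscle analysis row for the validation and ICU stages."""
    row = _slice_summary(table, muscle, view)
    row["comparison"] = _comparison_dict(table, muscle, view, config)
    row["icc_inter_operator"] = _icc_result_dict(
        _inter_operator_icc(table, muscle, view, config)
    )
    for op in (1, 2):
        _, reps = replicate_matrix(table, muscle, view, op)
        row[f"icc_intra_operator{op}"] = _icc_result_dict(
            icc_oneway(reps, alpha=config.alpha)
        )
    _, mat = operator_matrix(table, muscle, view, level="means")
    ba = bland_altman(mat[:, 0], mat[:, 1])
    row["bland_altman"] = {
        "bias_kpa": ba.bias,
        "sd_diff_kpa": ba.sd_diff,
        "loa_low_kpa": ba.loa_low,
        "loa_high_kpa": ba.loa_high,
        "n_pairs": ba.n_pairs,
    }
    return row, mat


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all configured stages; see the module docstring."""
    boot_seed = _derived_seeds(config.seed, 4)[3]
    report = StudyReport(
        provenance={
            "package": "swerel",
            "version": __version__,
            "seed": config.seed,
            "bootstrap_seed": boot_seed,
            "icc_mode": config.icc_mode,
            "icc_variant": config.icc_variant,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
    )

    muscles: list[str] = []
    training_icc: dict[str, dict[str, IccResult]] = {}

    if config.training is not None:
        try:
            table = _load_cohort(config.training)
            muscles = [m for m in dict.fromkeys(table.frame["muscle"])]
            views = list(dict.fromkeys(table.frame["view"]))
            for muscle in muscles:
                for view in views:
                    row = _slice_summary(table, muscle, view)
                    row["comparison"] = _comparison_dict(table, muscle, view, config)
                    res = _inter_operator_icc(table, muscle, view, config)
                    row["icc_inter_operator"] = _icc_result_dict(res)
                    training_icc.setdefault(muscle, {})[view] = res
                    report.training.append(row)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("training", str(exc), report) from exc

        try:
            selected = select_best_view(training_icc, tie_policy=config.tie_policy)
        except Exception as exc:  # noqa: BLE001
            raise StageError("view_selection", str(exc), report) from exc
        selected.update(config.view_overrides)
        report.selected_views = selected
    else:
        report.selected_views = dict(config.view_overrides)

    for stage, source in (("validation", config.validation), ("icu", config.icu)):
        if source is None:
            continue
        try:
            table = _load_cohort(source)
            stage_muscles = list(dict.fromkeys(table.frame["muscle"]))
            rows = []
            for muscle in stage_muscles:
                view = report.selected_views.get(muscle, "longitudinal")
                row, mat = _reliability_row(table, muscle, view, config)
                if stage == "icu":
                    boot = bootstrap_icc_probability(
                        mat,
                        threshold=config.bootstrap_threshold,
                        n_boot=config.n_boot,
                        seed=boot_seed,
                    )
                    row["bootstrap"] = {
                        "threshold": boot.threshold,
                        "n_boot": boot.n_boot,
                        "seed": boot.seed,
                        "probability": boot.probability,
                        "n_degenerate": boot.n_degenerate,
                        "icc_quantiles": boot.icc_quantiles,
                    }
                rows.append(row)
            getattr(report, stage).extend(rows)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(stage, str(exc), report) from exc

    return report


# ---------------------------------------------------------------------------
# YAML configuration

#: Commented template for `swerel run --config`.
CONFIG_TEMPLATE = """\
# swerel study configuration
# Every cohort is either a synthetic spec (as below) or a path to a
# long-format CSV: `training: path/to/training.csv`.
seed: 0                      # global seed; cohort/bootstrap substreams derive from it
icc_mode: means              # 'means' (triplicate means) or 'replicates' (full ANOVA)
icc_variant: agreement       # 'agreement' (absolute) or 'consistency'
alpha: 0.05                  # significance level for CIs and normality gates
bootstrap_threshold: 0.8     # ICC cut-off for the bootstrap probability
n_boot: 10000                # bootstrap resamples
tie_policy: prefer_longitudinal   # or 'ci_overlap'
# view_overrides:            # force a view regardless of the training comparison
#   rectus_femoris: transverse
training:
  n_subjects: 16
  missing_rate: 0.0
  n_replicates: 3
  # components: list of variance-component entries; 'view' may be omitted
  # to apply the entry to both views of that muscle.
  components:
    - {muscle: diaphragm, view: longitudinal, grand_mean_kpa: 19.7,
       sigma2_subject: 33.2, sigma2_operator: 1.0, sigma2_interaction: 1.7,
       sigma2_residual: 4.1}
validation:
  n_subjects: 15
  missing_rate: 0.03
icu:
  n_subjects: 12
  missing_rate: 0.03
"""


def _components_from_yaml(entries) -> dict:
    out = {}
    for e in entries or []:
        vc = VarianceComponents(
            grand_mean_kpa=float(e["grand_mean_kpa"]),
            sigma2_subject=float(e["sigma2_subject"]),
            sigma2_operator=float(e["sigma2_operator"]),
            sigma2_interaction=float(e["sigma2_interaction"]),
            sigma2_residual=float(e["sigma2_residual"]),
        )
        views = [e["view"]] if "view" in e else ["longitudinal", "transverse"]
        for view in views:
            out[(e["muscle"], view)] = vc
    return out


def config_from_yaml(path: str | Path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file (see CONFIG_TEMPLATE).

    Synthetic cohorts without an explicit ``seed`` get one derived from
    the global seed; defaults (including per-muscle variance components)
    come from :func:`default_study_config`.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))
    defaults = default_study_config(seed)
    cohorts = {}
    for name in ("training", "validation", "icu"):
        entry = raw.get(name)
        if entry is None:
            cohorts[name] = None
            continue
        if isinstance(entry, str):
            cohorts[name] = entry
            continue
        default_spec = getattr(defaults, name)
        components = _components_from_yaml(entry.get("components"))
        cohorts[name] = CohortSpec(
            cohort=name,
            n_subjects=int(entry.get("n_subjects", default_spec.n_subjects)),
            muscles=tuple(entry.get("muscles", default_spec.muscles)),
            views=tuple(entry.get("views", default_spec.views)),
            n_replicates=int(entry.get("n_replicates", default_spec.n_replicates)),
            missing_rate=float(entry.get("missing_rate", default_spec.missing_rate)),
            components=components or default_spec.components,
            seed=int(entry.get("seed", default_spec.seed)),
        )
    return StudyConfig(
        seed=seed,
        training=cohorts["training"],
        validation=cohorts["validation"],
        icu=cohorts["icu"],
        icc_mode=raw.get("icc_mode", "means"),
        icc_variant=raw.get("icc_variant", "agreement"),
        alpha=float(raw.get("alpha", 0.05)),
        bootstrap_threshold=float(raw.get("bootstrap_threshold", 0.8)),
        n_boot=int(raw.get("n_boot", 10_000)),
        tie_policy=raw.get("tie_policy", "prefer_longitudinal"),
        view_overrides=dict(raw.get("view_overrides", {})),
    )


# ---------------------------------------------------------------------------
# Report serialisation


def _stage_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.json_normalize(rows, sep=".") if rows else pd.DataFrame()


def write_report(
    report: StudyReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("json", "markdown", "csv_bundle"),
) -> list[Path]:
    """Write the report as machine-readable JSON and human tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    if "csv_bundle" in formats:
        for stage in ("training", "validation", "icu"):
            rows = getattr(report, stage)
            if rows:
                path = out_dir / f"{stage}.csv"
                _stage_frame(rows).to_csv(path, index=False)
                written.append(path)
        if report.selected_views:
            path = out_dir / "selected_views.csv"
            pd.DataFrame(
                sorted(report.selected_views.items()), columns=["muscle", "view"]
            ).to_csv(path, index=False)
            written.append(path)
    if "markdown" in formats:
        path = out_dir / "report.md"
        path.write_text(render_markdown(report))
        written.append(path)
    return written


def read_report(path: str | Path) -> StudyReport:
    """Load a JSON report back into a :class:`StudyReport`."""
    return StudyReport.from_dict(json.loads(Path(path).read_text()))


def render_markdown(report: StudyReport) -> str:
    """Human-readable report: one table per executed stage."""
    parts = ["# Shear-wave elastography reliability report", ""]
    prov = report.provenance
    parts.append(
        f"Generated by swerel {prov.get('version', '?')} "
        f"(seed {prov.get('seed', '?')}, ICC mode {prov.get('icc_mode', '?')})."
    )
    parts.append("")

    def icc_cell(d: dict) -> str:
        return f"{d['estimate']:.2f} [{d['ci_low']:.2f} to {d['ci_high']:.2f}] ({d['band']})"

    if report.training:
        parts += ["## Training set: view comparison", ""]
        parts.append(
            "| Muscle | View | n (repl.) | Op1 mean (SD) kPa | Op2 mean (SD) kPa "
            "| p | Inter-operator ICC |"
        )
        parts.append("|---|---|---|---|---|---|---|")
        for r in report.training:
            parts.append(
                f"| {r['muscle']} | {r['view']} | {r['n_replicate_level']} "
                f"| {r['operator1_mean_kpa']:.1f} ({r['operator1_sd_kpa']:.1f}) "
                f"| {r['operator2_mean_kpa']:.1f} ({r['operator2_sd_kpa']:.1f}) "
                f"| {r['comparison']['p_value']:.2f} "
                f"| {icc_cell(r['icc_inter_operator'])} |"
            )
        parts.append("")
    if report.selected_views:
        parts += ["## Selected views", ""]
        parts.append("| Muscle | View |")
        parts.append("|---|---|")
        for muscle, view in sorted(report.selected_views.items()):
            parts.append(f"| {muscle} | {view} |")
        parts.append("")
    for stage, title in (
        ("validation", "Validation set (healthy subjects)"),
        ("icu", "Critically ill patients"),
    ):
        rows = getattr(report, stage)
        if not rows:
            continue
        parts += [f"## {title}", ""]
        header = (
            "| Muscle | n (repl.) | Op1 mean (SD) kPa | Op2 mean (SD) kPa | p "
            "| Inter-op ICC | Intra-op1 ICC | Intra-op2 ICC |"
        )
        cols = 8
        if stage == "icu":
            header += " P(ICC >= thr) |"
            cols += 1
        parts.append(header)
        parts.append("|" + "---|" * cols)
        for r in rows:
            line = (
                f"| {r['muscle']} | {r['n_replicate_level']} "
                f"| {r['operator1_mean_kpa']:.1f} ({r['operator1_sd_kpa']:.1f}) "
                f"| {r['operator2_mean_kpa']:.1f} ({r['operator2_sd_kpa']:.1f}) "
                f"| {r['comparison']['p_value']:.2f} "
                f"| {icc_cell(r['icc_inter_operator'])} "
                f"| {icc_cell(r['icc_intra_operator1'])} "
                f"| {icc_cell(r['icc_intra_operator2'])} |"
            )
            if stage == "icu":
                line += f" {r['bootstrap']['probability'] * 100:.0f}% |"
            parts.append(line)
        parts.append("")
        parts.append(
            "Bland-Altman: "
            + "; ".join(
                f"{r['muscle']} bias {r['bland_altman']['bias_kpa']:.2f} kPa, "
                f"LoA [{r['bland_altman']['loa_low_kpa']:.2f}, "
                f"{r['bland_altman']['loa_high_kpa']:.2f}]"
                for r in rows
            )
        )
        parts.append("")
    return "\n".join(parts)
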