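"""End-to-end orchestration: synth -> prep -> derive -> model -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) and a
single global seed that fans out to per-stage seeds by fixed offsets.
Every run directory is self-describing: it contains the echoed config,
the cohort manifest, per-patient vitals/doses/derived CSVs, the model
feature table, per-outcome model summaries as JSON, ranking and
direction-of-effect matrices shaped like the familiar summary tables,
partial-dependence curves as CSV, Guyton venous-return diagrams per
drug, and a log of row counts and flags at each stage boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .hemodynamics import (
    CardiacFunctionCurve,
    GuytonDiagram,
    HemoConstants,
    derive_all,
    guyton_diagram,
)
from .modeling import ModelResult, ModelSpec, run_all_outcomes
from .preprocessing import build_feature_table, impute_patient_median
from .schema import DRUGS, OUTCOMES
from .synthetic import Cohort, PatientProfile, SyntheticConfig, generate_cohort

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "run_pipeline",
    "render_tables",
    "write_cohort",
    "read_cohort",
    "guyton_diagrams_from_results",
]

log = logging.getLogger(__name__)

#: Drugs rendered as Guyton venous-return figures (the drugs with the
#: clearest venous-side stories).
GUYTON_FIGURE_DRUGS = (
    "epinephrine", "norepinephrine", "milrinone", "vasopressin", "calcium_chloride",
)

#: Human-readable labels for rendered tables.
DISPLAY_NAMES = {
    "time_s": "Time",
    "patient_id": "Patient",
    "age_years": "Age",
    "weight_kg": "Weight",
    "epinephrine": "Epinephrine",
    "norepinephrine": "Norepinephrine",
    "milrinone": "Milrinone",
    "vasopressin": "Vasopressin",
    "phenylephrine": "Phenylephrine",
    "calcium_chloride": "Calcium chloride",
    "nitroprusside": "Nitroprusside",
    "nicardipine": "Nicardipine",
    "mcfp": "Mean Circulatory Filling Pressure",
    "rv": "Venous Resistance",
    "svri": "Indexed Systemic Vascular Resistance",
    "ci": "Cardiac Index",
    "coer": "Cerebral Oxygen Extraction",
    "roer": "Renal Oxygen Extraction",
}

ARROWS = {"increase": "↑", "decrease": "↓", "neutral": ""}

#: Per-stage seed offsets fanned out from the global seed.
STAGE_SEED_OFFSETS = {"synth": 0, "model": 500_001}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration for one reproducible end-to-end run.

    Exactly one input mode is active: a synthetic block (the generator's
    study conditions) or paths to real exported data (a vitals directory,
    a doses directory and a cohort manifest).
    """

    seed: int = 0
    synthetic: SyntheticConfig | None = None
    vitals_dir: str | None = None
    doses_dir: str | None = None
    manifest_path: str | None = None
    constants: HemoConstants = field(default_factory=HemoConstants)
    model: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        real = self.vitals_dir or self.doses_dir or self.manifest_path
        if self.synthetic is not None and real:
            raise ValueError("configure either the synthetic block or real-data paths, not both")
        if self.synthetic is None and not (
            self.vitals_dir and self.doses_dir and self.manifest_path
        ):
            raise ValueError(
                "real-data mode needs vitals_dir, doses_dir and manifest_path; "
                "or provide a synthetic block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.get("synthetic")
        return cls(
            seed=int(raw.get("seed", 0)),
            synthetic=SyntheticConfig.from_dict(synth) if synth is not None else None,
            vitals_dir=raw.get("vitals_dir"),
            doses_dir=raw.get("doses_dir"),
            manifest_path=raw.get("manifest_path"),
            constants=HemoConstants(**raw.get("constants", {})),
            model=ModelSpec(**raw.get("model", {})),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "vitals_dir": self.vitals_dir,
            "doses_dir": self.doses_dir,
            "manifest_path": self.manifest_path,
            "constants": dataclasses.asdict(self.constants),
            "model": dataclasses.asdict(self.model),
        }


# --------------------------------------------------------------------------
# Cohort I/O
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path, config: SyntheticConfig | None = None) -> None:
    """Write per-patient vitals/doses CSVs plus a JSON cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for profile, vitals, doses in zip(*cohort):
        vitals.to_csv(out / f"vitals_{profile.patient_id}.csv", index=False)
        doses.to_csv(out / f"doses_{profile.patient_id}.csv", index=False)
    manifest = {
        "profiles": [dataclasses.asdict(p) for p in cohort.profiles],
        "config": config.to_dict() if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(
    vitals_dir: str | Path,
    doses_dir: str | Path | None = None,
    manifest_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (or matching layout)."""
    vdir = Path(vitals_dir)
    ddir = Path(doses_dir) if doses_dir else vdir
    mpath = Path(manifest_path) if manifest_path else vdir / "manifest.json"
    manifest = json.loads(mpath.read_text())
    profiles = [PatientProfile(**p) for p in manifest["profiles"]]
    vitals, doses = [], []
    for p in profiles:
        vitals.append(pd.read_csv(vdir / f"vitals_{p.patient_id}.csv"))
        doses.append(pd.read_csv(ddir / f"doses_{p.patient_id}.csv"))
    return Cohort(profiles, vitals, doses)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def render_tables(results: Mapping[str, ModelResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary matrices: importance ranking and direction of effect.

    The ranking matrix has one column per outcome and eight rows: the
    features time + the seven actively dosed drugs, each column ordered
    from most to least important. The direction matrix has one row per
    drug and one cell per outcome in {up-arrow, down-arrow, blank}.
    """
    if len(results) < len(OUTCOMES):
        raise ValueError(f"expected {len(OUTCOMES)} model results, got {len(results)}")
    table_drugs = [d for d in DRUGS if d != "phenylephrine"]
    ranked_features = ["time_s", *table_drugs]

    ranking = {}
    for outcome in OUTCOMES:
        order = [f for f, _ in results[outcome].importance_ranking if f in ranked_features]
        ranking[DISPLAY_NAMES[outcome]] = [DISPLAY_NAMES[f] for f in order]
    ranking_df = pd.DataFrame(ranking)

    directions = {
        DISPLAY_NAMES[outcome]: [
            ARROWS[results[outcome].directions[d]] for d in table_drugs
        ]
        for outcome in OUTCOMES
    }
    direction_df = pd.DataFrame(directions, index=[DISPLAY_NAMES[d] for d in table_drugs])
    return ranking_df, direction_df


def guyton_diagrams_from_results(
    results: Mapping[str, ModelResult],
    f_max_L_min: float,
    drugs: Sequence[str] = GUYTON_FIGURE_DRUGS,
) -> dict[str, tuple[GuytonDiagram, GuytonDiagram]]:
    """Baseline vs drug-on venous-return diagrams per drug.

    The baseline condition takes MCFP and Rv from the low end of each
    drug's partial-dependence sweep and the drug-on condition from the
    high end, so the figures visualize exactly what the fitted models
    say the drug does to the venous return line.
    """
    out = {}
    curve = CardiacFunctionCurve(f_max_L_min=f_max_L_min)
    for drug in drugs:
        _, mcfp_pd = results["mcfp"].pd_curves[drug]
        _, rv_pd = results["rv"].pd_curves[drug]
        base_mcfp, on_mcfp = float(mcfp_pd[0]), float(mcfp_pd[-1])
        base_rv, on_rv = float(rv_pd[0]), float(rv_pd[-1])
        if min(base_rv, on_rv) <= 0 or min(base_mcfp, on_mcfp) <= 0:
            log.warning("skipping Guyton figure for %s: non-positive MCFP/Rv", drug)
            continue
        out[drug] = (
            guyton_diagram(base_mcfp, base_rv, curve, condition_label="baseline"),
            guyton_diagram(on_mcfp, on_rv, curve, condition_label=f"{drug} on"),
        )
    return out


def _markdown_table(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def _plot_guyton_pair(pair: tuple[GuytonDiagram, GuytonDiagram], drug: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for diag, color in zip(pair, ("tab:blue", "tab:red")):
        ax.plot(diag.rap_grid, diag.vr_line, color=color, label=f"VR, {diag.condition_label}")
        ax.plot(diag.rap_grid, diag.cardiac_curve, color=color, linestyle="--",
                label=f"cardiac, {diag.condition_label}")
        if diag.operating_point is not None:
            ax.plot(*diag.operating_point, "o", color=color)
    ax.set_xlabel("Right atrial pressure (mmHg)")
    ax.set_ylabel("Flow (L/min)")
    ax.set_title(f"Venous return and cardiac output: {DISPLAY_NAMES.get(drug, drug)}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("synth")
def _stage_synth(config: RunConfig, out: Path) -> Cohort:
    synth_cfg = dataclasses.replace(
        config.synthetic, seed=config.seed + STAGE_SEED_OFFSETS["synth"]
    )
    cohort = generate_cohort(synth_cfg)
    write_cohort(cohort, out / "cohort", synth_cfg)
    log.info("synth: %d patients x %d rows", len(cohort.profiles),
             len(cohort.vitals[0]) if cohort.vitals else 0)
    return cohort


@_stage("load")
def _stage_load(config: RunConfig) -> Cohort:
    return read_cohort(config.vitals_dir, config.doses_dir, config.manifest_path)


@_stage("prep")
def _stage_prep(cohort: Cohort) -> list[pd.DataFrame]:
    imputed = [impute_patient_median(v) for v in cohort.vitals]
    n_flagged = sum(len(v.attrs.get("fully_missing_signals", [])) for v in imputed)
    log.info("prep: imputed %d frames, %d fully-missing signal flags", len(imputed), n_flagged)
    return imputed


@_stage("derive")
def _stage_derive(
    cohort: Cohort, imputed: list[pd.DataFrame], constants: HemoConstants, out: Path
) -> list[pd.DataFrame]:
    derived = []
    ddir = out / "derived"
    ddir.mkdir(parents=True, exist_ok=True)
    for profile, vitals in zip(cohort.profiles, imputed):
        frame = derive_all(profile, vitals, constants)
        frame.to_csv(ddir / f"derived_{profile.patient_id}.csv", index=False)
        derived.append(frame)
    log.info("derive: %d frames", len(derived))
    return derived


@_stage("model")
def _stage_model(table: pd.DataFrame, config: RunConfig) -> dict[str, ModelResult]:
    spec = dataclasses.replace(config.model, seed=config.seed + STAGE_SEED_OFFSETS["model"])
    results = run_all_outcomes(table, spec)
    log.info("model: fitted %d outcomes on %d rows", len(results), len(table))
    return results


@_stage("report")
def _stage_report(
    results: dict[str, ModelResult], derived: list[pd.DataFrame], out: Path
) -> None:
    rdir = out / "results"
    rdir.mkdir(parents=True, exist_ok=True)
    for outcome, res in results.items():
        (rdir / f"model_{outcome}.json").write_text(json.dumps(res.to_dict(), indent=2))
        rows = []
        for drug, (grid, values) in res.pd_curves.items():
            for g, v in zip(grid, values):
                rows.append({"drug": drug, "dose": g, "partial_dependence": v})
        pd.DataFrame(rows).to_csv(rdir / f"pd_{outcome}.csv", index=False)

    ranking_df, direction_df = render_tables(results)
    ranking_df.to_csv(rdir / "table_importance_ranking.csv", index=False)
    direction_df.to_csv(rdir / "table_direction_of_effect.csv")
    (rdir / "table_importance_ranking.md").write_text(_markdown_table(ranking_df))
    (rdir / "table_direction_of_effect.md").write_text(
        _markdown_table(direction_df.reset_index(names="Drug"))
    )

    co_all = np.concatenate([d["co"].to_numpy() for d in derived])
    f_max = float(np.nanmedian(co_all)) * 1.3
    for drug, pair in guyton_diagrams_from_results(results, f_max).items():
        pair[0].to_frame().assign(condition="baseline").pipe(
            lambda a: pd.concat([a, pair[1].to_frame().assign(condition="drug_on")])
        ).to_csv(rdir / f"guyton_{drug}.csv", index=False)
        _plot_guyton_pair(pair, drug, rdir / f"guyton_{drug}.png")
    log.info("report: wrote tables, %d outcome summaries", len(results))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the directory.

    Any stage failure raises :class:`PipelineStageError` naming the
    stage; outputs written before the failure remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("guyton_bedside")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        (out / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict()))
        if config.synthetic is not None:
            cohort = _stage_synth(config, out)
        else:
            cohort = _stage_load(config)
        imputed = _stage_prep(cohort)
        derived = _stage_derive(cohort, imputed, config.constants, out)
        table = build_feature_table(cohort.profiles, imputed, cohort.doses, derived)
        table.to_csv(out / "features.csv", index=False)
        results = _stage_model(table, config)
        _stage_report(results, derived, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
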