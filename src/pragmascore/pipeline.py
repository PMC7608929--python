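"""End-to-end orchestration: score, agreement, progression, power, report.

``run_full_analysis`` runs the whole reanalysis on a synthetic cohort (or
a user-supplied long cohort table), producing

* a subscore summary in the published table layout (mean +/- SD at SOS and
  EOS, paired EOS-SOS delta),
* one mixed-model fixed-effects table per outcome (8 CT outcomes + FEV1
  %predicted),
* intra-observer ICCs and cross-system correlation / Bland-Altman
  agreement,
* optional power curves,

all mirrored into a machine-readable ``report.json`` (every number printed
in the human-readable ``report.md`` is rendered from that JSON; runs with
identical seeds produce byte-identical JSON).  Scores are rounded to 2
decimals and coefficients/p-values to 3-4 decimals, half-up, at render
time only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman_standardized, correlate_systems, icc_two_way
from .cohort_synth import CohortConfig, SyntheticCohort, generate_cohort, generate_rescore
from .power_sim import PowerCurve, disease_scenario, find_n_for_power, mucus_plugging_scenario
from .progression import DEFAULT_TRANSFORMS, OUTCOMES, LmmFit, fit_lmm, progression_summary

__all__ = ["RunConfig", "run_full_analysis", "round_half_up"]

#: Pretty names for the report's mixed-model tables.
TERM_LABELS = {
    "intercept": "(Intercept)",
    "time_eos": "patient CT status (EOS)",
    "group_placebo": "Treatment group (placebo)",
    "tobra_yes": "Tobramycin treatment (Yes)",
    "time_eos:group_placebo": "patient CT status (EOS): Treatment group (placebo)",
    "time_eos:tobra_yes": "patient CT status (EOS): Tobramycin treatment (Yes)",
    "group_placebo:tobra_yes": "Treatment group (placebo): Tobramycin treatment (Yes)",
}

AGREEMENT_SUBSCORES = ("bronchiectasis", "mucus_plugging", "disease")


@dataclass
class RunConfig:
    out_dir: str | Path = "pragmascore_run"
    synthetic: bool = True
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | Path | None = None  # long table CSV when synthetic=False
    rescores_path: str | Path | None = None
    outcomes: Sequence[str] = OUTCOMES
    transforms: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    alpha: float = 0.05
    seed: int = 0
    icc_target: float = 0.85
    n_rescored: int = 20
    run_power: bool = False
    power_grid: Sequence[int] = tuple(range(60, 221, 10))
    power_replicates: int = 400
    make_plots: bool = False

    def __post_init__(self) -> None:
        missing = [o for o in self.outcomes if o not in self.transforms]
        if missing:
            raise ValueError(f"transform map does not cover outcomes {missing}")


def round_half_up(value: float, digits: int) -> float:
    """Decimal half-up rounding (report rendering only)."""
    if value != value:  # nan
        return value
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _tidy_scores_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Split outcome names like ``pragma_disease`` back into system/subscore."""
    rows = long[long["outcome"].str.startswith(("pragma_", "cfct_"))].copy()
    parts = rows["outcome"].str.split("_", n=1, expand=True)
    rows["system"], rows["subscore"] = parts[0], parts[1]
    return rows[["patient_id", "visit", "system", "subscore", "value"]]


@_stage("summary")
def _summary_table(scores: pd.DataFrame) -> list[dict]:
    out = []
    for (system, subscore), block in scores.groupby(["system", "subscore"], sort=True):
        wide = block.pivot_table(index="patient_id", columns="visit", values="value")
        entry = {"system": system, "subscore": subscore}
        for visit in ("SOS", "EOS"):
            if visit in wide.columns:
                vals = wide[visit].dropna()
                entry[f"{visit.lower()}_mean"] = float(vals.mean())
                entry[f"{visit.lower()}_sd"] = float(vals.std(ddof=1))
                entry[f"{visit.lower()}_n"] = int(vals.size)
        if {"SOS", "EOS"}.issubset(wide.columns):
            paired = wide.dropna(subset=["SOS", "EOS"])
            delta = paired["EOS"] - paired["SOS"]
            entry["delta_mean"] = float(delta.mean())
            entry["delta_se"] = float(delta.std(ddof=1) / np.sqrt(len(delta))) if len(delta) > 1 else float("nan")
            entry["n_paired"] = int(len(delta))
        out.append(entry)
    return out


@_stage("progression")
def _fit_all(long: pd.DataFrame, config: RunConfig) -> list[LmmFit]:
    fits = []
    for outcome in config.outcomes:
        if not (long["outcome"] == outcome).any():
            continue
        fits.append(fit_lmm(long, outcome, transform=config.transforms[outcome], terms="full"))
    return fits


@_stage("agreement")
def _agreement(scores: pd.DataFrame, rescores: pd.DataFrame | None, config: RunConfig) -> dict:
    result: dict = {"icc": [], "cross_system": [], "bland_altman": []}
    if rescores is not None and not rescores.empty:
        for (system, subscore), block in rescores.groupby(["system", "subscore"], sort=True):
            wide = block.pivot_table(
                index=["patient_id", "visit"], columns="occasion", values="value"
            ).dropna()
            if len(wide) < 2 or wide.shape[1] < 2:
                continue
            icc = icc_two_way(wide.to_numpy())
            result["icc"].append(
                {
                    "system": system,
                    "subscore": subscore,
                    "icc": None if icc.degenerate else icc.icc,
                    "band": icc.band,
                    "degenerate": icc.degenerate,
                    "reason": icc.reason,
                    "n_subjects": icc.n_subjects,
                }
            )
    wide_all = scores.pivot_table(
        index=["patient_id", "visit"], columns=["system", "subscore"], values="value"
    )
    for subscore in AGREEMENT_SUBSCORES:
        for visit in ("SOS", "EOS"):
            try:
                sub = wide_all.xs(visit, level="visit")
                pair = sub[[("pragma", subscore), ("cfct", subscore)]].dropna()
            except KeyError:
                continue
            if len(pair) < 3:
                continue
            x = pair[("pragma", subscore)].to_numpy()
            y = pair[("cfct", subscore)].to_numpy()
            try:
                corr = correlate_systems(x, y, sqrt_transform=True)
                ba = bland_altman_standardized(x, y)
            except ValueError:
                continue
            result["cross_system"].append(
                {
                    "subscore": subscore,
                    "visit": visit,
                    "r": corr.r,
                    "p_value": corr.p_value,
                    "slope": corr.slope,
                    "intercept": corr.intercept,
                    "n": corr.n,
                    "sqrt_transform": True,
                }
            )
            result["bland_altman"].append(
                {
                    "subscore": subscore,
                    "visit": visit,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "n": len(pair),
                }
            )
    return result


@_stage("power")
def _power(config: RunConfig) -> list[dict]:
    curves = []
    for name, scenario in (
        ("pragma_disease", disease_scenario()),
        ("pragma_mucus_plugging", mucus_plugging_scenario()),
    ):
        curve = find_n_for_power(
            scenario,
            target_power=0.9,
            n_grid=list(config.power_grid),
            n_replicates=config.power_replicates,
            seed=config.seed,
        )
        curves.append(
            {
                "outcome": name,
                "reduction": scenario.reduction,
                "target_power": curve.target_power,
                "n_star": curve.n_star,
                "grid": [
                    {"n_per_arm": e.n_per_arm, "power": e.power, "mc_se": e.mc_se}
                    for e in curve.estimates
                ],
            }
        )
    return curves


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full reanalysis and write ``report.json`` / ``report.md``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        cohort_config = config.cohort_config
        if cohort_config.seed != config.seed:
            from dataclasses import replace

            cohort_config = replace(cohort_config, seed=config.seed)
        cohort = generate_cohort(cohort_config)
        long = cohort.long_table(list(config.outcomes))
        scores = cohort.scores[cohort.scores["system"].isin(("pragma", "cfct"))]
        n_visits = len(cohort.scorable_visits())
        rescores = (
            generate_rescore(
                cohort, config.icc_target, min(config.n_rescored, n_visits), seed=config.seed + 1
            )
            if n_visits >= 2
            else None
        )
    else:
        if config.cohort_path is None:
            raise StageError("stage 'input' failed: cohort_path required when synthetic=False")
        long = pd.read_csv(config.cohort_path, dtype={"patient_id": str})
        scores = _tidy_scores_from_long(long)
        rescores = (
            pd.read_csv(config.rescores_path, dtype={"patient_id": str})
            if config.rescores_path
            else None
        )

    fits = _fit_all(long, config)
    summary = _summary_table(scores)
    agreement = _agreement(scores, rescores, config)
    prog = progression_summary(fits, alpha=config.alpha, expected=config.outcomes)
    power = _power(config) if config.run_power else []

    report = {
        "meta": {
            "package": "pragmascore",
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "synthetic": config.synthetic,
            "n_patients": int(long["patient_id"].nunique()),
            "n_observation_rows": int(len(long)),
        },
        "subscore_summary": summary,
        "lmm": [f.to_dict() for f in fits],
        "progression_summary": prog.to_dict(orient="records"),
        "agreement": agreement,
        "power": power,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    (out_dir / "report.md").write_text(_render_markdown(report))
    with (out_dir / "run.log").open("w") as log:
        log.write(f"pragmascore {__version__}\nseed={config.seed}\n")
        log.write(f"numpy={np.__version__} pandas={pd.__version__}\n")
    if config.make_plots:
        _write_plots(scores, out_dir)
    return report


def _write_plots(scores: pd.DataFrame, out_dir: Path) -> None:
    from .agreement import bland_altman_plot, scatter_plot

    wide = scores.pivot_table(
        index=["patient_id", "visit"], columns=["system", "subscore"], values="value"
    )
    for subscore in AGREEMENT_SUBSCORES:
        try:
            pair = wide[[("pragma", subscore), ("cfct", subscore)]].dropna()
        except KeyError:
            continue
        if len(pair) < 3:
            continue
        x = pair[("pragma", subscore)].to_numpy()
        y = pair[("cfct", subscore)].to_numpy()
        try:
            corr = correlate_systems(x, y, sqrt_transform=True)
            ba = bland_altman_standardized(x, y)
        except ValueError:
            continue
        scatter_plot(x, y, corr, out_dir / f"scatter_{subscore}.png", title=subscore)
        bland_altman_plot(ba, out_dir / f"bland_altman_{subscore}.png", title=subscore)


def _render_markdown(report: dict) -> str:
    lines = ["# pragmascore report", ""]
    meta = report["meta"]
    lines.append(
        f"pragmascore {meta['version']} | seed {meta['seed']} | "
        f"{meta['n_patients']} patients | alpha {meta['alpha']}"
    )
    lines += ["", "## Subscore summary (mean ± SD; delta = mean paired EOS-SOS)", ""]
    lines.append("| System | Subscore | SOS | EOS | delta | SE delta |")
    lines.append("|---|---|---|---|---|---|")
    for row in report["subscore_summary"]:
        sos = (
            f"{round_half_up(row['sos_mean'], 2)}±{round_half_up(row['sos_sd'], 2)}"
            if "sos_mean" in row
            else "-"
        )
        eos = (
            f"{round_half_up(row['eos_mean'], 2)}±{round_half_up(row['eos_sd'], 2)}"
            if "eos_mean" in row
            else "-"
        )
        delta = round_half_up(row["delta_mean"], 2) if "delta_mean" in row else "-"
        dse = round_half_up(row["delta_se"], 2) if "delta_se" in row else "-"
        lines.append(f"| {row['system']} | {row['subscore']} | {sos} | {eos} | {delta} | {dse} |")

    lines += ["", "## Linear mixed-effects models", ""]
    for fit in report["lmm"]:
        lines.append(f"### {fit['outcome']} (transform: {fit['transform']})")
        lines.append("")
        lines.append("| Term | Value | Standard Error | p-value |")
        lines.append("|---|---|---|---|")
        for term in fit["terms"]:
            fe = fit["fixed_effects"][term]
            lines.append(
                f"| {TERM_LABELS.get(term, term)} | {round_half_up(fe['estimate'], 3)} "
                f"| {round_half_up(fe['se'], 3)} | {round_half_up(fe['p_value'], 4)} |"
            )
        lines.append("")

    lines += ["## Progression summary", ""]
    lines.append("| Outcome | Time effect | SE | p | progressing |")
    lines.append("|---|---|---|---|---|")
    for row in report["progression_summary"]:
        lines.append(
            f"| {row['outcome']} | {round_half_up(row['time_estimate'], 3)} | "
            f"{round_half_up(row['se'], 3)} | {round_half_up(row['p_value'], 4)} | "
            f"{'yes' if row['progressing'] else 'no'} |"
        )

    agr = report["agreement"]
    if agr["icc"]:
        lines += ["", "## Intra-observer ICC", ""]
        lines.append("| System | Subscore | ICC | Band |")
        lines.append("|---|---|---|---|")
        for row in agr["icc"]:
            icc = "-" if row["degenerate"] else round_half_up(row["icc"], 3)
            lines.append(f"| {row['system']} | {row['subscore']} | {icc} | {row['band']} |")
    if agr["cross_system"]:
        lines += ["", "## Cross-system agreement (sqrt scale)", ""]
        lines.append("| Subscore | Visit | r | p | BA bias | LoA |")
        lines.append("|---|---|---|---|---|---|")
        ba_by_key = {(b["subscore"], b["visit"]): b for b in agr["bland_altman"]}
        for row in agr["cross_system"]:
            ba = ba_by_key.get((row["subscore"], row["visit"]))
            loa = (
                f"[{round_half_up(ba['loa_low'], 2)}, {round_half_up(ba['loa_high'], 2)}]"
                if ba
                else "-"
            )
            bias = round_half_up(ba["bias"], 3) if ba else "-"
            lines.append(
                f"| {row['subscore']} | {row['visit']} | {round_half_up(row['r'], 3)} | "
                f"{round_half_up(row['p_value'], 4)} | {bias} | {loa} |"
            )

    if report["power"]:
        lines += ["", "## Power curves (target 0.9)", ""]
        lines.append("| Outcome | Reduction | n* per arm |")
        lines.append("|---|---|---|")
        for curve in report["power"]:
            lines.append(
                f"| {curve['outcome']} | {curve['reduction']} | {curve['n_star']} |"
            )
    lines.append("")
    return "\n".join(lines)
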