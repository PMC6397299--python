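"""End-to-end orchestration: simulate -> fit-counts -> fit-dose -> risk -> report.

``run_pipeline`` executes every analysis stage on a cohort (read from CSV or
generated synthetically), writes a diffable report bundle of CSV/JSON files,
and embeds the full config echo, a config hash and the seeds in every
artifact so any number in the bundle can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import MonteCarloDoseFit, monte_carlo_fit, predict_curve
from .item_risk import SOFT_VS_HARD_GROUPING, risk_ratio_table
from .load_model import (
    TABLE1_MODEL_SET,
    aic_table,
    anova_posthoc,
    check_overdispersion,
    cod_ordering_test,
)
from .records import Cohort, read_cohort, summarize_cohort, write_cohort
from .simulate import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: Union[str, Path]
    input_csv: Optional[Union[str, Path]] = None
    synthetic: Optional[SyntheticConfig] = None
    mc_reps: int = 1000
    mc_seed: int = 0
    variants: tuple[str, ...] = ("trust_KD", "distrust_KD")
    draw: str = "uniform"
    reference_weight: Optional[float] = None
    risk_reference: str = "hard_plastic"
    models: tuple[tuple[str, ...], ...] = TABLE1_MODEL_SET
    quiet: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv or synthetic must be given")

    def to_jsonable(self) -> dict[str, Any]:
        # output_dir is deliberately excluded: the hash identifies the
        # scientific configuration, not where the bundle lands
        d: dict[str, Any] = {
            "input_csv": str(self.input_csv) if self.input_csv else None,
            "synthetic": dataclasses.asdict(self.synthetic) if self.synthetic else None,
            "mc_reps": self.mc_reps,
            "mc_seed": self.mc_seed,
            "variants": list(self.variants),
            "draw": self.draw,
            "reference_weight": self.reference_weight,
            "risk_reference": self.risk_reference,
            "models": [list(m) for m in self.models],
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    syn = raw.get("synthetic")
    if syn is not None:
        from .simulate import SpeciesRow

        if "species_table" in syn:
            syn["species_table"] = tuple(SpeciesRow(*row) for row in syn["species_table"])
        raw["synthetic"] = SyntheticConfig(**syn)
    if "variants" in raw:
        raw["variants"] = tuple(raw["variants"])
    if "models" in raw:
        raw["models"] = tuple(tuple(m) for m in raw["models"])
    return RunConfig(**raw)


@dataclass
class AnalysisReport:
    """In-memory results of a pipeline run (also written to the bundle)."""

    cohort: Cohort
    summary: Any
    aic: Any
    cod_order: Any
    adequacy: Any
    anova: dict[str, Any]
    dose: dict[str, MonteCarloDoseFit]
    curves: dict[str, Any]
    risk: Any
    risk_soft_hard: Any
    dose_estimable: bool
    version: str
    config: RunConfig


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all stages and write the report bundle; deterministic per config."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "mc_seed": config.mc_seed,
        "config": config.to_jsonable(),
    }

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.input_csv is not None:
            cohort = read_cohort(config.input_csv)
            truth = None
        else:
            cohort, truth = generate_cohort(config.synthetic)
            write_cohort(cohort, outdir / "cohort.csv")
            _write_json(
                outdir / "truth.json",
                {
                    "causes": truth.causes,
                    "config": dataclasses.asdict(truth.config),
                    **provenance,
                },
            )
    except Exception as err:
        raise StageError(f"cohort stage failed: {err}") from err
    if not config.quiet:
        logger.info("cohort ready: %d birds (%.1fs)", len(cohort), time.time() - t0)

    # --- stage: summary ----------------------------------------------------
    summary = summarize_cohort(cohort)
    _write_json(outdir / "summary.json", {**dataclasses.asdict(summary), **provenance})

    # --- stage: fit-counts -------------------------------------------------
    try:
        aic = aic_table(cohort, config.models)
        best_with_cod = next(
            (lbl for lbl, _ in aic.rows if "cod" in aic.fits[lbl].terms), None
        )
        fit_for_order = aic.fits[best_with_cod] if best_with_cod else None
        cod_order = cod_ordering_test(fit_for_order) if fit_for_order else None
        adequacy = check_overdispersion(fit_for_order, cohort) if fit_for_order else None
        anova = {}
        for m in ("count", "mass", "volume"):
            try:
                anova[m] = anova_posthoc(cohort, m)
            except ValueError:
                anova[m] = None  # too few birds per COD group
    except Exception as err:
        raise StageError(f"fit-counts stage failed: {err}") from err
    aic.to_frame().to_csv(outdir / "aic_table.csv", index=False)
    if cod_order is not None:
        _write_json(
            outdir / "cod_ordering.json",
            {
                "model": best_with_cod,
                "contrasts": {
                    k: {"estimate": v[0], "se": v[1], "p_value": v[2]}
                    for k, v in cod_order.contrasts.items()
                },
                "ordering_satisfied": cod_order.ordering_satisfied,
                "adequacy_p": adequacy.p_value,
                **provenance,
            },
        )
    _write_json(
        outdir / "anova.json",
        {
            m: (
                {
                    "F": a.f_statistic,
                    "p": a.p_value,
                    "pairwise_p": a.pairwise_p,
                    "group_means": a.group_means,
                }
                if a is not None
                else {"not_estimable": True}
            )
            for m, a in anova.items()
        },
    )
    if not config.quiet:
        logger.info("fit-counts done (%.1fs)", time.time() - t0)

    # --- stage: fit-dose ---------------------------------------------------
    dose: dict[str, MonteCarloDoseFit] = {}
    curves: dict[str, Any] = {}
    n_by_cod = cohort.n_by_cod()
    dose_estimable = len(cohort) >= 10 and n_by_cod["KND"] >= 1 and (
        n_by_cod["Ind"] + n_by_cod["KD"] >= 1
    )
    if dose_estimable:
        try:
            for variant in config.variants:
                mc = monte_carlo_fit(
                    cohort,
                    variant=variant,
                    n_reps=config.mc_reps,
                    seed=config.mc_seed,
                    draw=config.draw,
                )
                dose[variant] = mc
                curve = predict_curve(mc, config.reference_weight)
                curves[variant] = curve
                tag = variant.lower()
                pd.DataFrame(
                    {
                        "rep": range(len(mc.fits)),
                        "b0": [f.b0 for f in mc.fits],
                        "b1": [f.b1 for f in mc.fits],
                        "b2": [f.b2 for f in mc.fits],
                        "se_b1": [f.se_b1 for f in mc.fits],
                        "converged": [f.converged for f in mc.fits],
                    }
                ).to_csv(outdir / f"dose_{tag}_reps.csv", index=False)
                _write_json(
                    outdir / f"dose_{tag}_median.json",
                    {
                        "variant": variant,
                        "median_b0": mc.median_b0,
                        "median_b1": mc.median_b1,
                        "median_b2": mc.median_b2,
                        "frac_slope_significant": mc.frac_slope_significant,
                        "n_converged": mc.n_converged,
                        "n_reps": mc.n_reps,
                        "reference_weight": curve.reference_weight,
                        **provenance,
                    },
                )
                pd.DataFrame(
                    {
                        "n_items": curve.n_grid,
                        "p_median": curve.p_median,
                        "p_min": curve.p_min,
                        "p_max": curve.p_max,
                    }
                ).to_csv(outdir / f"dose_{tag}_curve.csv", index=False)
                # slope-distribution summary (histogram + significant fraction)
                b1s = np.array([f.b1 for f in mc.converged_fits])
                hist, edges = np.histogram(b1s, bins=20)
                _write_json(
                    outdir / f"dose_{tag}_slopes.json",
                    {
                        "bin_edges": edges,
                        "counts": hist,
                        "frac_slope_significant": mc.frac_slope_significant,
                    },
                )
        except Exception as err:
            raise StageError(f"fit-dose stage failed: {err}") from err
    else:
        _write_json(
            outdir / "dose_not_estimable.json",
            {
                "reason": "too few birds or no outcome variation for the dose model",
                "n_birds": len(cohort),
                "n_by_cod": n_by_cod,
                "partial": True,
                **provenance,
            },
        )
    if not config.quiet:
        logger.info("fit-dose done (%.1fs)", time.time() - t0)

    # --- stage: risk -------------------------------------------------------
    try:
        risk = risk_ratio_table(cohort, reference=config.risk_reference)
    except ValueError as err:
        risk = None
        _write_json(outdir / "risk_not_estimable.json", {"reason": str(err), "partial": True})
    risk_soft = None
    if risk is not None:
        risk.to_frame().to_csv(outdir / "risk.csv", index=False)
        try:
            risk_soft = risk_ratio_table(
                cohort, reference="hard", grouping=SOFT_VS_HARD_GROUPING
            )
            risk_soft.to_frame().to_csv(outdir / "risk_soft_vs_hard.csv", index=False)
        except ValueError:
            risk_soft = None

    # --- human-readable summary -------------------------------------------
    lines = [
        f"debrisdose {__version__}  (config {provenance['config_hash']}, seed {config.mc_seed})",
        f"cohort: {len(cohort)} birds; {summary.n_ingesting} ingesting "
        f"({summary.pct_ingesting:.1f}%); COD {n_by_cod}",
        f"best count model by AIC: {aic.best_label}",
    ]
    if cod_order is not None:
        lines.append(
            "COD ordering KND < Ind < KD satisfied: "
            f"{cod_order.ordering_satisfied}"
        )
    for variant, mc in dose.items():
        lines.append(
            f"dose-response [{variant}]: median b1 = {mc.median_b1:.4f} per item, "
            f"significant in {mc.frac_slope_significant:.0%} of {mc.n_converged} reps"
        )
    if not dose_estimable:
        lines.append("dose-response: NOT ESTIMABLE on this cohort")
    if risk is not None:
        try:
            balloon = risk.row("balloon")
            lines.append(
                f"balloon risk ratio vs {risk.reference}: {balloon.ratio_vs_reference:.1f}"
            )
        except KeyError:
            pass
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    _write_json(outdir / "report.json", {"summary_lines": lines, **provenance})
    if not config.quiet:
        logger.info("pipeline complete (%.1fs)", time.time() - t0)

    return AnalysisReport(
        cohort=cohort,
        summary=summary,
        aic=aic,
        cod_order=cod_order,
        adequacy=adequacy,
        anova=anova,
        dose=dose,
        curves=curves,
        risk=risk,
        risk_soft_hard=risk_soft,
        dose_estimable=dose_estimable,
        version=__version__,
        config=config,
    )
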