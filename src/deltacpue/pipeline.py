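"""End-to-end orchestration: simulate/ingest → clean → stratify → fit →
index → report, driven by a YAML config with a single seed.

Every stage writes its artifacts into the run directory and appends a line
to ``run.log``; stages never mutate earlier outputs, so a run directory is
append-only and reproducible byte-for-byte given the same config and seed
(the optimizer uses fixed starting points and tolerances).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import reporting
from .areas import AreaScheme, AreaAssigner
from .cleaning import CleaningRules, clean_records
from .glmm import (ModelSpec, dispersion_diagnostic, fit_binomial_glmm,
                   fit_gamma_glmm, positive_subset, stepwise_select)
from .index import predict_year_effects
from .records import read_logbook, write_logbook
from .simulate import default_truth, generate_logbook, save_truth

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    output_dir: str = "run"
    input_csv: str | None = None        # if None, simulate
    n_sets: int = 2000                  # simulation size when simulating
    species: tuple = ("blue", "mako")
    areas: tuple = ("West", "Southwest", "South", "East")
    candidate_terms: tuple = ("month", "fleet", "observer")
    prediction_policy: str = "reference"
    anomaly_threshold: float = 3.0
    bias_correct: bool = False
    stepwise: bool = True
    min_positive_sets: int = 30
    min_vessels: int = 2
    cleaning: dict = field(default_factory=dict)    # CleaningRules overrides
    area_scheme: dict = field(default_factory=dict)  # AreaScheme overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("species", "areas", "candidate_terms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        for key in ("year_range", "hooks_range", "latitude_range",
                    "longitude_range"):
            if key in raw.get("cleaning", {}):
                raw["cleaning"][key] = tuple(raw["cleaning"][key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def cleaning_rules(self) -> CleaningRules:
        return CleaningRules(**self.cleaning)

    def scheme(self) -> AreaScheme:
        return AreaScheme(**self.area_scheme)


def _log(fh, stage, message):
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {message}"
    fh.write(line + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    results: dict = {}
    with open(log_path, "a", encoding="utf-8") as log:
        try:
            # --- simulate / ingest ------------------------------------
            stage = "ingest"
            if config.input_csv is not None:
                data = read_logbook(config.input_csv)
                _log(log, stage, f"read {len(data)} sets from "
                                 f"{config.input_csv}")
            else:
                stage = "simulate"
                truth = default_truth(seed=config.seed, n_sets=config.n_sets)
                data, truth = generate_logbook(truth)
                write_logbook(data, outdir / "logbook.csv")
                save_truth(truth, outdir / "truth.json")
                _log(log, stage, f"simulated {len(data)} sets "
                                 f"(seed={config.seed})")

            # --- clean -------------------------------------------------
            stage = "clean"
            report = clean_records(data, config.cleaning_rules(),
                                   keep_rejected=True)
            report.to_json(outdir / "cleaning_report.json")
            write_logbook(report.retained, outdir / "cleaned.csv")
            if report.rejected is not None and len(report.rejected):
                report.rejected.to_csv(outdir / "quarantine.csv", index=False)
            _log(log, stage,
                 f"retained {report.n_retained}/{report.n_input} "
                 f"({100 * report.retained_fraction:.1f}%) "
                 f"rejections={report.rejections_by_rule}")
            cleaned = report.retained

            # --- stratify ---------------------------------------------
            stage = "stratify"
            tagged = AreaAssigner(config.scheme()).fit_transform(cleaned)
            n_none = int(tagged["area"].isna().sum()
                         + (tagged["area"].values == None).sum())  # noqa: E711
            tagged = tagged[~tagged["area"].isna()
                            & (tagged["area"].values != None)]  # noqa: E711
            tagged.to_csv(outdir / "stratified.csv", index=False)
            _log(log, stage, f"assigned areas; dropped {n_none} sets "
                             "outside all areas")

            # --- fit + index ------------------------------------------
            fits_dir = outdir / "fits"
            index_dir = outdir / "index"
            fits_dir.mkdir(exist_ok=True)
            index_dir.mkdir(exist_ok=True)
            combined = []
            status: dict = {}
            for species in config.species:
                for area in config.areas:
                    key = f"{species}_{area}"
                    sub = tagged[tagged["area"] == area]
                    pos = positive_subset(sub, species)
                    if (len(pos) < config.min_positive_sets
                            or sub["vessel_id"].nunique() < config.min_vessels
                            or sub["year"].nunique() < 2):
                        status[key] = "insufficient data"
                        _log(log, "fit", f"{key}: insufficient data "
                             f"({len(pos)} positive sets)")
                        continue
                    stage = f"fit:{key}"
                    if config.stepwise:
                        spec_b, table_b = stepwise_select(
                            sub, "binomial", config.candidate_terms,
                            species=species, area=area)
                        spec_g, table_g = stepwise_select(
                            pos, "gamma", config.candidate_terms,
                            species=species, area=area)
                        table_b.to_csv(fits_dir / f"{key}_binomial_bic.csv",
                                       index=False)
                        table_g.to_csv(fits_dir / f"{key}_gamma_bic.csv",
                                       index=False)
                    else:
                        terms = ("year",) + tuple(config.candidate_terms)
                        spec_b = ModelSpec("binomial", terms,
                                           species=species, area=area)
                        spec_g = ModelSpec("gamma", terms,
                                           species=species, area=area)
                    fit_b = fit_binomial_glmm(sub, spec_b)
                    fit_g = fit_gamma_glmm(pos, spec_g)
                    for part, fit in (("binomial", fit_b), ("gamma", fit_g)):
                        with open(fits_dir / f"{key}_{part}.json", "w",
                                  encoding="utf-8") as fh:
                            json.dump(fit.to_dict(), fh, indent=2)
                    diag = dispersion_diagnostic(sub, species=species)
                    _log(log, stage,
                         f"binomial BIC={fit_b.bic:.1f} "
                         f"gamma BIC={fit_g.bic:.1f} "
                         f"dispersion_slope="
                         f"{diag.slope if diag.available else 'n/a'}")
                    if not (fit_b.converged and fit_g.converged):
                        status[key] = "fit did not converge"
                        _log(log, stage, f"{key}: non-converged fit, "
                                         "no index emitted")
                        continue

                    stage = f"index:{key}"
                    series = predict_year_effects(
                        fit_b, fit_g, policy=config.prediction_policy,
                        bias_correct=config.bias_correct,
                        ratio_threshold=config.anomaly_threshold)
                    series.to_csv(index_dir / f"{key}.csv")
                    frame = series.frame.copy()
                    frame.insert(0, "area", area)
                    frame.insert(0, "species", species)
                    combined.append(frame)
                    status[key] = "ok"
                    _log(log, stage,
                         f"{len(series.frame)} years, "
                         f"{int(series.frame['anomaly_flag'].sum())} flagged")
            with open(index_dir / "status.json", "w", encoding="utf-8") as fh:
                json.dump(status, fh, indent=2)
            if combined:
                pd.concat(combined, ignore_index=True).to_csv(
                    outdir / "index.csv", index=False)

            # --- report ------------------------------------------------
            stage = "report"
            rep_dir = outdir / "report"
            rep_dir.mkdir(exist_ok=True)
            reporting.effort_summary(tagged, "year").to_csv(
                rep_dir / "effort_by_year.csv", index=False)
            reporting.effort_summary(tagged, "month").to_csv(
                rep_dir / "effort_by_month.csv", index=False)
            reporting.effort_summary(tagged, "fleet").to_csv(
                rep_dir / "effort_by_fleet.csv", index=False)
            reporting.shark_ratio(tagged).to_csv(
                rep_dir / "shark_ratio.csv", index=False)
            reporting.composition(tagged, ["area", "fleet"]).to_csv(
                rep_dir / "composition.csv", index=False)
            _log(log, stage, "report tables written")
        except Exception as exc:
            _log(log, stage, f"FAILED: {exc}")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
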