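"""End-to-end orchestration: ingest -> match -> summarise -> model.

A single YAML config names every input (occurrence CSV, climatology and
depth-series NetCDF, thermal-limit CSV, group table, optional edits file)
and the analysis settings; :func:`run_pipeline` then produces the full set
of documented intermediate and final artifacts in the output directory:

* ``records.csv`` / ``rejects.csv`` — normalised occurrences + QC log
* ``matched.csv`` — one row per record with all temperature measures,
  best values and exclusion reasons
* ``match_report.csv`` — per-measure match accounting
* ``affinity.csv`` — per-species x per-measure thermal affinity
* ``limits.csv`` — one aggregated Tmax per species with functional group
* ``margins.csv`` / ``margin_table.csv`` — safety margins and the
  group x affinity-bin summary
* ``model_report.json`` — polynomial fits, comparisons and vertices
* ``manifest.json`` — config hash, stage counts, package version

Identical config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .affinity_stats import summarize_affinities
from .grid_data import load_climatology, load_depth_series
from .grid_match import MEASURES, assign_best_temperature, match_climatology, match_depth_series, match_report
from .margin_analysis import (
    FORMS,
    ThermalLimitModel,
    bin_margin_table,
    compare_models,
    safety_margins,
)
from .occurrence_qc import read_occurrences
from .tmax_prep import assign_functional_group, prepare_limits

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run."""

    occurrences: str
    climatology: str | list[str]
    depth_series: str
    limits: str
    groups: str
    outdir: str
    edits: str | None = None
    columns: dict | None = None
    measures: list[str] = dc_field(default_factory=lambda: list(MEASURES))
    margin_measure: str = "grid_t_at_depth"
    model_measures: list[str] = dc_field(
        default_factory=lambda: ["clim_best", "grid_t_at_depth"]
    )
    model_forms: list[str] = dc_field(default_factory=lambda: list(FORMS))
    nekton_best: str = "sst"
    seed: int = 0

    def input_paths(self) -> dict[str, str]:
        paths = {
            "occurrences": self.occurrences,
            "depth_series": self.depth_series,
            "limits": self.limits,
            "groups": self.groups,
        }
        clim = self.climatology if isinstance(self.climatology, list) else [self.climatology]
        for i, p in enumerate(clim):
            paths[f"climatology[{i}]"] = p
        if self.edits:
            paths["edits"] = self.edits
        return paths


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PipelineError(f"config {path}: expected a mapping at top level")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config {path}: unknown keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise PipelineError(f"config {path}: {exc}") from exc


def validate_config(config: RunConfig) -> dict:
    """Schema and cross-field checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            errors.append(f"{name}: path does not exist: {p}")
    bad = set(config.measures) - set(MEASURES)
    bad |= set(config.model_measures) - set(MEASURES)
    if bad:
        errors.append(f"unknown measures {sorted(bad)}; valid: {MEASURES}")
    if config.margin_measure not in MEASURES:
        errors.append(f"unknown margin_measure {config.margin_measure!r}; valid: {MEASURES}")
    bad_forms = set(config.model_forms) - set(FORMS)
    if bad_forms:
        errors.append(f"unknown model forms {sorted(bad_forms)}; valid: {list(FORMS)}")
    if config.nekton_best not in ("sst", "sbt"):
        errors.append("nekton_best must be 'sst' or 'sbt'")
    if not errors:
        try:
            limits = pd.read_csv(config.limits)
            groups = pd.read_csv(config.groups)
            missing = set(limits["species_id"]) - set(groups["species_id"])
            if missing:
                warnings.append(
                    f"{len(missing)} species in limits absent from group table "
                    f"(e.g. {sorted(missing)[:3]}); they will be ungrouped"
                )
        except Exception as exc:  # cross-check is best-effort
            warnings.append(f"could not cross-check limits/groups: {exc}")
    return {"errors": errors, "warnings": warnings}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _config_hash(config: RunConfig) -> str:
    # outdir excluded: the same analysis written elsewhere is the same run
    blob = json.dumps(
        {k: getattr(config, k) for k in RunConfig.__dataclass_fields__ if k != "outdir"},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest."""
    report = validate_config(config)
    if report["errors"]:
        raise PipelineError("config: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("config: %s", w)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "thermaffin_version": __version__,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("ingest")
    def _ingest():
        records, rejects = read_occurrences(config.occurrences, columns=config.columns)
        _write_csv(records, outdir / "records.csv")
        _write_csv(rejects, outdir / "rejects.csv")
        manifest["stages"]["ingest"] = {
            "rows_in": len(records) + len(rejects),
            "records": len(records),
            "rejected": len(rejects),
        }
        return records

    records = _ingest

    @stage("load_grids")
    def _grids():
        clim = load_climatology(config.climatology)
        series = load_depth_series(config.depth_series)
        return clim, series

    clim, series = _grids

    @stage("limits")
    def _limits():
        raw_limits = pd.read_csv(config.limits)
        attributes = pd.read_csv(config.groups)
        edits = []
        if config.edits:
            with open(config.edits) as fh:
                edits = yaml.safe_load(fh) or []
        limits = prepare_limits(raw_limits, attributes, edits=edits)
        _write_csv(limits, outdir / "limits.csv")
        manifest["stages"]["limits"] = {
            "records_in": len(raw_limits),
            "species": len(limits),
            "ungrouped": int(limits["group_key"].isna().sum()),
            "edits_applied": len(edits),
        }
        groups_df = assign_functional_group(attributes)
        return limits, groups_df

    limits, groups_df = _limits

    @stage("match")
    def _match():
        matched = match_climatology(records, clim)
        matched = match_depth_series(matched, series)
        matched = assign_best_temperature(
            matched,
            groups_df[["species_id", "group_key"]].dropna(),
            nekton_best=config.nekton_best,
        )
        _write_csv(matched, outdir / "matched.csv")
        rep = match_report(matched, measures=config.measures)
        _write_csv(rep, outdir / "match_report.csv")
        manifest["stages"]["match"] = {
            "records": len(matched),
            "per_measure_matched": dict(
                zip(rep["measure"], rep["n_matched"].astype(int))
            ),
        }
        return matched

    matched = _match

    @stage("affinity")
    def _affinity():
        affinities = summarize_affinities(matched, measures=config.measures)
        _write_csv(affinities, outdir / "affinity.csv")
        manifest["stages"]["affinity"] = {
            "species_x_measure_rows": len(affinities),
            "species_with_any_match": int(
                (affinities.groupby("species_id")["n_matched"].max() > 0).sum()
            ),
        }
        return affinities

    affinities = _affinity

    @stage("model")
    def _model():
        model_report: dict = {"fits": {}, "comparisons": {}}
        fits_by_measure: dict = {}
        for measure in config.model_measures:
            aff = affinities.loc[
                (affinities["measure"] == measure) & affinities["mean"].notna(),
                ["species_id", "mean"],
            ]
            data = limits.merge(aff, on="species_id", how="inner").dropna(
                subset=["group_key"]
            )
            fits = {}
            for form in config.model_forms:
                try:
                    fits[form] = ThermalLimitModel(
                        data["tmax"].to_numpy(),
                        data["mean"].to_numpy(),
                        group=data["group_key"].to_numpy(),
                        form=form,
                    ).fit()
                except ValueError as exc:
                    model_report["fits"].setdefault(measure, {})[form] = {
                        "error": str(exc)
                    }
            for form, fit in fits.items():
                model_report["fits"].setdefault(measure, {})[form] = fit.to_dict()
            pairs = [("pooled", "additive"), ("additive", "interaction")]
            for nested, full in pairs:
                if nested in fits and full in fits:
                    cmpres = compare_models(fits[nested], fits[full])
                    model_report["comparisons"][f"{measure}:{full}_vs_{nested}"] = {
                        "df_num": cmpres.df_num,
                        "df_den": cmpres.df_den,
                        "f_statistic": cmpres.f_statistic,
                        "p_value": cmpres.p_value,
                        "delta_rsquared": cmpres.delta_rsquared,
                    }
            fits_by_measure[measure] = fits
        with open(outdir / "model_report.json", "w") as fh:
            json.dump(model_report, fh, indent=2, sort_keys=True)
        manifest["stages"]["model"] = {
            m: sorted(f for f in fits) for m, fits in fits_by_measure.items()
        }
        return model_report

    _model

    @stage("margins")
    def _margins():
        margins = safety_margins(limits, affinities, measure=config.margin_measure)
        margins = margins.dropna(subset=["group_key"]) if "group_key" in margins else margins
        _write_csv(margins, outdir / "margins.csv")
        table = bin_margin_table(margins)
        _write_csv(table, outdir / "margin_table.csv")
        manifest["stages"]["margins"] = {
            "species_margined": len(margins),
            "species_in_limits": len(limits),
        }

    _margins

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
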