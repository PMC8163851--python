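"""End-to-end orchestration: simulate -> exposure -> cohort -> fits -> impact.

A :class:`RunConfig` (YAML-loadable) names the inputs/outputs, stage
toggles and model specification; :func:`run` executes the enabled stages
and writes a machine-readable manifest (seed, input hashes, per-stage row
counts) so that a fixed configuration and seed reproduce the run
byte-for-byte apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import exposure as exp_mod
from . import impact as impact_mod
from . import synthetic as syn_mod
from .clogit import ConditionalLogit, fit_nonlinear_exposure, fit_subgroup_interaction
from .design import TermSpec

__all__ = ["RunConfig", "run", "default_terms", "MAIN_MODEL_COMBOS"]

#: fully adjusted, mutually adjusted covariate specification
def default_terms() -> list:
    return [
        TermSpec("fire", "linear", increment=1.0),
        TermSpec("nonfire", "linear", increment=1.0),
        TermSpec("age_band", "categorical"),
        TermSpec("temperature", "ns", df=3),
        TermSpec("humidity", "ns", df=3),
        TermSpec("conception_month", "ns", df=4),
        TermSpec("conception_year", "categorical"),
    ]


#: the four adjustment combinations of the main-analysis table
MAIN_MODEL_COMBOS = {
    "crude": dict(adjusted=False, mutual=False),
    "crude_mutual": dict(adjusted=False, mutual=True),
    "adjusted": dict(adjusted=True, mutual=False),
    "adjusted_mutual": dict(adjusted=True, mutual=True),
}


def combo_terms(adjusted: bool, mutual: bool) -> list:
    terms = [TermSpec("fire", "linear", increment=1.0)]
    if mutual:
        terms.append(TermSpec("nonfire", "linear", increment=1.0))
    if adjusted:
        terms += [
            TermSpec("age_band", "categorical"),
            TermSpec("temperature", "ns", df=3),
            TermSpec("humidity", "ns", df=3),
            TermSpec("conception_month", "ns", df=4),
            TermSpec("conception_year", "categorical"),
        ]
    return terms


def terms_from_spec(spec: list) -> list:
    """Ordered term list from a YAML model block."""
    out = []
    for item in spec:
        out.append(
            TermSpec(
                name=item["name"],
                kind=item.get("kind", "linear"),
                df=item.get("df"),
                increment=float(item.get("increment", 1.0)),
            )
        )
    return out


@dataclass
class RunConfig:
    out_dir: str = "firegest_run"
    seed: int = 0
    world: dict = field(default_factory=dict)  # WorldConfig overrides
    fields_nc: Optional[str] = None  # coarse monthly stack (NetCDF) instead of simulating
    satellite_nc: Optional[str] = None  # annual fine reference raster (NetCDF)
    events_csv: Optional[str] = None  # event table instead of simulating
    period: tuple = (2000, 2014)
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "exposure": True,
            "cohort": True,
            "fit": True,
            "impact": True,
        }
    )
    model: Optional[list] = None  # YAML term list; default_terms() if None
    fit_main_combos: bool = True
    fit_subsets: bool = False
    fit_subgroups: bool = False
    fit_nonlinear: bool = False
    nonlinear_df: int = 3
    subgroups: tuple = ("age_group3", "education", "residence", "insurance")
    subsets: tuple = cohort_mod.SUBSET_FLAGS
    write_fields_nc: bool = False
    write_exposure_csv: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def validate(self) -> None:
        paths = (
            ("fields_nc", self.fields_nc),
            ("satellite_nc", self.satellite_nc),
            ("events_csv", self.events_csv),
        )
        for key, path in paths:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key} refers to a missing path: {path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "input_hashes": {},
    }
    for p in (config.fields_nc, config.satellite_nc, config.events_csv):
        if p is not None:
            manifest["input_hashes"][str(p)] = _sha256(p)

    world_cfg = syn_mod.WorldConfig.from_dict({"rng_seed": config.seed, **config.world})

    # --- simulate -------------------------------------------------------
    fields = calibrated = events = None
    if config.stages.get("simulate", True):
        world = syn_mod.simulate_world(world_cfg)
        fields, calibrated = world.fields, world.calibrated
        events = world.cohort.events
        syn_mod.write_events(events, out / "events.csv")
        if config.write_fields_nc:
            exp_mod.write_fields(fields.coarse, out / "fields_coarse.nc")
            exp_mod.write_fields(fields.satellite.to_dataset(), out / "satellite.nc")
        manifest["stages"]["simulate"] = {
            "n_mothers": int(world.cohort.mothers.shape[0]),
            "n_events": int(len(events)),
            "n_losses": int((events["outcome"] == "loss").sum()),
        }
    else:
        if config.fields_nc and config.satellite_nc:
            coarse = exp_mod.read_fields(config.fields_nc)
            sat = exp_mod.read_fields(config.satellite_nc)["pm_satellite"]
            fields = syn_mod.SimulatedFields(
                coarse, sat, sat["lat"].values, sat["lon"].values
            )
        if config.events_csv:
            events = syn_mod.read_events(config.events_csv)

    # --- exposure -------------------------------------------------------
    series = None
    if config.stages.get("exposure", True):
        if calibrated is None:
            if fields is None or events is None:
                raise ValueError(
                    "exposure stage needs simulated or supplied fields and events"
                )
            calibrated = syn_mod.calibrated_from_fields(fields)
        cl = events[["cluster_id", "lat", "lon"]].drop_duplicates("cluster_id").sort_values("cluster_id")
        series = exp_mod.extract_at_points(calibrated, cl["lat"].to_numpy(), cl["lon"].to_numpy())
        # cluster_id -> row index in the series
        cid_to_row = {cid: i for i, cid in enumerate(cl["cluster_id"])}
        events = events.assign(_point=events["cluster_id"].map(cid_to_row))
        if config.write_exposure_csv:
            exp_mod.exposure_table(series, cl["cluster_id"].to_numpy()).to_csv(
                out / "exposure_monthly.csv", index=False
            )
        manifest["stages"]["exposure"] = {
            "n_points": int(len(cl)),
            "n_months": int(series.months.size),
            "n_clamped_rho": exp_mod._CLAMP_LOG["n_clamped"],
        }

    # --- cohort ---------------------------------------------------------
    matched = None
    if config.stages.get("cohort", True):
        if series is None:
            raise ValueError("cohort stage requires the exposure stage")
        matched = cohort_mod.build_matched_cohort(
            events, series, config.period, point_col="_point"
        )
        cohort_mod.write_matched(matched, out / "matched.csv")
        d = matched.data
        manifest["stages"]["cohort"] = {
            "n_sets": matched.n_sets,
            "n_cases": int((d["is_case"] == 1).sum()),
            "n_controls": int((d["is_case"] == 0).sum()),
            "n_events": int(len(d)),
            "n_cases_unmatched": matched.n_cases_unmatched,
        }

    # --- fit ------------------------------------------------------------
    fits: dict = {}
    if config.stages.get("fit", True):
        if matched is None:
            raise ValueError("fit stage requires the cohort stage")
        d = matched.data
        terms = terms_from_spec(config.model) if config.model else default_terms()
        fit_meta = {}

        def _fit(tag, frame, tm):
            res = ConditionalLogit.from_dataframe(frame, tm).fit()
            res.to_frame().to_csv(out / f"fit_{tag}.csv", index=False)
            fit_meta[tag] = {
                "llf": res.llf,
                "converged": res.converged,
                "iterations": res.niter,
                "n_sets": res.n_sets,
                "n_events": res.n_events,
            }
            fits[tag] = res
            return res

        if config.fit_main_combos:
            for tag, combo in MAIN_MODEL_COMBOS.items():
                _fit(tag, d, combo_terms(**combo))
        else:
            _fit("main", d, terms)

        if config.fit_subsets:
            for flag in config.subsets:
                sub = d[d[flag]]
                if sub.empty or sub["is_case"].sum() == 0:
                    continue
                # keep only sets that still have a case and a control
                ok = sub.groupby("set_id")["is_case"].agg(["sum", "count"])
                keep = ok[(ok["sum"] == 1) & (ok["count"] >= 2)].index
                sub = sub[sub["set_id"].isin(keep)]
                if sub["set_id"].nunique() >= 50:
                    _fit(f"subset_{flag}", sub, terms)

        if config.fit_subgroups:
            for gv in config.subgroups:
                sg = fit_subgroup_interaction(d, terms, "fire", gv)
                sg.table.to_csv(out / f"subgroup_{gv}.csv")
                fit_meta[f"subgroup_{gv}"] = {
                    "p_heterogeneity": sg.p_heterogeneity,
                    "lrt_statistic": sg.lrt_statistic,
                    "lrt_df": sg.lrt_df,
                }
                fits[f"subgroup_{gv}"] = sg

        if config.fit_nonlinear:
            curve = fit_nonlinear_exposure(d, terms, "fire", spline_df=config.nonlinear_df)
            curve.to_frame().to_csv(out / "exposure_response.csv", index=False)
            fit_meta["nonlinear"] = {"p_nonlinearity": curve.p_nonlinearity}
            fits["nonlinear"] = curve

        with open(out / "fits.json", "w") as fh:
            json.dump(fit_meta, fh, indent=2)
        manifest["stages"]["fit"] = {k: v for k, v in fit_meta.items()}

    # --- impact ---------------------------------------------------------
    if config.stages.get("impact", True):
        key = "adjusted_mutual" if "adjusted_mutual" in fits else "main"
        if key not in fits:
            raise ValueError("impact stage requires a mutually adjusted fit")
        res = fits[key]
        ci = res.conf_int()
        d = matched.data
        af_f = impact_mod.af_result(
            "fire",
            res.params["fire"],
            d["fire"].mean(),
            impact_mod.TMREL_FIRE,
            (ci.loc["fire", "lower"], ci.loc["fire", "upper"]),
        )
        af_n = impact_mod.af_result(
            "nonfire",
            res.params["nonfire"],
            d["nonfire"].mean(),
            impact_mod.TMREL_NONFIRE,
            (ci.loc["nonfire", "lower"], ci.loc["nonfire", "upper"]),
        )
        comp = impact_mod.compare_sources(af_f.af, af_n.af, res.params["fire"], res.params["nonfire"])
        impact_mod.impact_table([af_f, af_n]).to_csv(out / "impact.csv", index=False)
        summary = {"fire": af_f.to_dict(), "nonfire": af_n.to_dict(), "comparison": comp.to_dict()}
        with open(out / "impact.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["stages"]["impact"] = comp.to_dict()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
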