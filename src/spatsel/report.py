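"""Descriptive statistics and end-to-end pipeline orchestration.

``run_pipeline`` executes simulate -> exposures -> correlation PCA ->
spike-and-slab selection (and, when configured, strip Kriging -> buffer ->
two-stage validation) from a single config, writing every table, a text
report per stage, and a structured log of seeds and hyperparameters so the
bundle regenerates bit-identically from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .exposure import build_exposure_matrix
from .kriging import buffer_filter, fit_kriging, krige_predict, two_stage_fit
from .pca import correlation_pca, loading_report, retain_components
from .selection import (
    MCMCSettings,
    NMIGHyperparams,
    SpikeSlabLogisticRegression,
)
from .simulate import STRIP_METALS, SimulationConfig, simulate_study

__all__ = ["DescriptiveSummary", "descriptive_stats", "run_pipeline"]


@dataclass
class DescriptiveSummary:
    """Sample descriptives: % outcome-positive, % male, median age."""

    n: int
    pct_ana_positive: float
    pct_male: float
    median_age: float
    decimals: int

    def to_row(self) -> dict:
        return {
            "n": self.n,
            "pct_ana_positive": self.pct_ana_positive,
            "pct_male": self.pct_male,
            "median_age": self.median_age,
        }


def _pct(k: int, n: int, decimals: int) -> float:
    v = round(100.0 * k / n, decimals)
    return float(v) if decimals > 0 else float(int(v))


def descriptive_stats(participants: pd.DataFrame, decimals: int = 1) -> DescriptiveSummary:
    """Percent positive / percent male / median age of a participant table.

    ``decimals`` controls percent rounding: 1 decimal for a full cohort,
    nearest integer (0) for small validation subsamples, per convention.
    """
    if participants.empty:
        raise ValueError("empty participant table")
    n = len(participants)
    out = DescriptiveSummary(
        n=n,
        pct_ana_positive=_pct(int(participants["ana"].sum()), n, decimals),
        pct_male=_pct(int(participants["gendernum"].sum()), n, decimals)
        if "gendernum" in participants else float("nan"),
        median_age=float(participants["CurAge"].median())
        if "CurAge" in participants else float("nan"),
        decimals=decimals,
    )
    return out


_MEDIA_ALIAS = {"soil": ("soil",), "gw": ("groundwater",),
                "joint": ("soil", "groundwater")}


def _write(path: Path, text: str) -> None:
    path.write_text(text if text.endswith("\n") else text + "\n")


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> dict:
    """Execute the configured analysis end to end.

    Config keys: ``seed`` (required), ``simulation`` (SimulationConfig fields),
    ``exposure`` (address_class, media alias, power), ``pca`` (threshold,
    cutoff), ``selection`` (design: "pcs"|"chemicals", mcmc sizes), and
    optional ``validation`` (buffer_km, chemicals, mcmc). Returns a manifest
    of written files plus key results; any stage failure raises with the
    stage name.
    """
    if isinstance(config, (str, Path)):
        from .io import load_config

        config = load_config(config)
    cfg = dict(config)
    if "seed" not in cfg:
        raise ValueError("pipeline config requires a master seed")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": [], "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as e:
                manifest["stages"][name] = "failed"
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            manifest["stages"][name] = "ok"
            return result
        return deco

    sim_cfg = SimulationConfig.from_dict(
        {"seed": cfg["seed"], **cfg.get("simulation", {})}
    )
    validation_cfg = cfg.get("validation")

    @stage("simulate")
    def study():
        return simulate_study(sim_cfg, include_strip=validation_cfg is not None)

    for name, df in (
        ("sites", study.sites), ("measurements", study.measurements),
        ("addresses", study.addresses), ("participants", study.participants),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        manifest["files"].append(p.name)

    exp_cfg = cfg.get("exposure", {})
    address_class = exp_cfg.get("address_class", "longest")
    media = _MEDIA_ALIAS[exp_cfg.get("media", "joint")]
    power = int(exp_cfg.get("power", 1))

    @stage("exposure")
    def exposures():
        m = study.measurements[study.measurements["medium"] != "strip"]
        return build_exposure_matrix(
            study.addresses, m, address_class=address_class, media=media, p=power
        )

    exposures.to_csv(out / "exposures.csv")
    manifest["files"].append("exposures.csv")

    pca_cfg = cfg.get("pca", {})
    threshold = float(pca_cfg.get("threshold", 0.80))
    cutoff = float(pca_cfg.get("cutoff", 0.30))

    @stage("pca")
    def pca_res():
        return correlation_pca(exposures)

    k, scores = retain_components(pca_res, threshold)
    rep = loading_report(pca_res, k, cutoff)
    _write(
        out / "pca_report.txt",
        f"correlation PCA ({address_class} address, media={exp_cfg.get('media', 'joint')}, "
        f"power={power}); {k} component(s) reach {100 * threshold:.0f}% variance\n"
        + rep.to_text(),
    )
    scores.to_csv(out / "pca_scores.csv")
    manifest["files"] += ["pca_report.txt", "pca_scores.csv"]
    manifest["n_components"] = k

    sel_cfg = cfg.get("selection", {})
    design_kind = sel_cfg.get("design", "pcs")
    mcmc = MCMCSettings(
        n_iter=int(sel_cfg.get("n_iter", 4000)),
        burn_in=int(sel_cfg.get("burn_in", 2000)),
        thin=int(sel_cfg.get("thin", 2)),
        n_chains=int(sel_cfg.get("n_chains", 1)),
        seed=int(cfg["seed"]) + 1,
    )
    personal_cols = [c for c in study.participants.columns
                     if c not in ("participant_id", "ana")]

    @stage("selection")
    def sel_est():
        if design_kind == "pcs":
            Xc = scores.reset_index(drop=True)
        elif design_kind == "chemicals":
            Xc = exposures.reset_index(drop=True)
        else:
            raise ValueError(f"unknown selection design {design_kind!r}")
        X = pd.concat(
            [study.participants[personal_cols].reset_index(drop=True), Xc], axis=1
        )
        est = SpikeSlabLogisticRegression(
            n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
            n_chains=mcmc.n_chains, random_state=mcmc.seed,
        )
        est.fit(X, study.participants["ana"].to_numpy())
        return est

    _write(out / "selection_report.txt", sel_est.summary_.to_text())
    sel_est.summary_.table.to_csv(out / "inclusion.csv")
    sel_est.samples_.to_frame().to_csv(out / "posterior.csv", index=False)
    manifest["files"] += ["selection_report.txt", "inclusion.csv", "posterior.csv"]

    desc_rows = {"full": descriptive_stats(study.participants, decimals=1).to_row()}

    if validation_cfg is not None:
        buffer_km = float(validation_cfg.get("buffer_km", 1.0))
        chems = list(validation_cfg.get("chemicals", STRIP_METALS[:4]))
        vmcmc = MCMCSettings(
            n_iter=int(validation_cfg.get("n_iter", 4000)),
            burn_in=int(validation_cfg.get("burn_in", 2000)),
            thin=int(validation_cfg.get("thin", 2)),
            n_chains=int(validation_cfg.get("n_chains", 1)),
            seed=int(cfg["seed"]) + 2,
        )
        v_class = validation_cfg.get("address_class", "first")
        strip_sites = study.sites[study.sites["medium"] == "strip"]
        strip_meas = study.measurements[study.measurements["medium"] == "strip"]

        @stage("validate")
        def vfit():
            addr = study.addresses[study.addresses["address_class"] == v_class]
            eligible = buffer_filter(addr, strip_sites, radius_km=buffer_km)
            if len(eligible) < 4:
                raise ValueError(
                    f"only {len(eligible)} participants within {buffer_km} km "
                    "of the strip"
                )
            kriged = {}
            for i, chem in enumerate(chems):
                sub = strip_meas[strip_meas["chemical"] == chem]
                if sub.empty:
                    raise ValueError(f"strip chemical {chem!r} not simulated")
                model = fit_kriging(
                    sub, seed=int(cfg["seed"]) + 100 + i,
                    mcmc={"n_iter": int(validation_cfg.get("krige_n_iter", 2000)),
                          "burn_in": int(validation_cfg.get("krige_burn_in", 1000))},
                )
                kriged[chem] = krige_predict(model, eligible)
            ids = eligible["participant_id"]
            psub = study.participants.set_index("participant_id").loc[ids]
            fit = two_stage_fit(
                psub["ana"].to_numpy(), kriged,
                personal=psub[personal_cols].reset_index(drop=True),
                mcmc=vmcmc,
            )
            return eligible, psub.reset_index(), fit

        eligible, psub, vres = vfit
        desc_rows[f"{v_class}_address"] = descriptive_stats(psub, decimals=0).to_row()
        _write(out / "validation_report.txt", vres.to_text())
        vres.summary.table.to_csv(out / "validation_inclusion.csv")
        manifest["files"] += ["validation_report.txt", "validation_inclusion.csv"]
        manifest["n_eligible"] = int(len(eligible))

    desc = pd.DataFrame.from_dict(desc_rows, orient="index")
    desc.index.name = "sample"
    desc.to_csv(out / "descriptives.csv")
    manifest["files"].append("descriptives.csv")

    log = {
        "package_version": __version__,
        "config": _jsonable(cfg),
        "simulation_config": _jsonable(asdict(sim_cfg)),
        "selection_mcmc": asdict(mcmc),
        "nmig_defaults": asdict(NMIGHyperparams()),
    }
    (out / "log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    manifest["files"].append("log.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
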