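"""Orchestration of the three canonical experiments.

``run_experiment`` chains simulate -> sensor stats -> first-level inversions ->
PEB -> model comparison for one of:

* ``crossover``   — drug vs placebo in healthy adults; 5-hypothesis comparison
  over which synaptic parameter set explains the drug effect, plus Bayesian
  model averaging over all parameter-set combinations;
* ``severity``    — baseline patient cohort; MMSE regressor on the blockade;
* ``progression`` — baseline vs follow-up completers; session + scan-interval
  regressors on the blockade.

Every output carries the config hash and seed; reports are reproducible
byte-for-byte given the same config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohorts import CohortData, CohortSpec, generate, write_cohort
from .densities import GaussianDensity
from .errors import InvalidParameterError
from .forward import default_observation
from .params import ModelConfig, default_priors
from .peb import (
    PEBDesign, PEBResult, PEBSettings, all_combinations_bma, fit_peb,
    model_space_compare,
)
from .sensor import amplitude_table, amplitude_vs_covariate, mmn_records, paired_t
from .vl import InversionSettings, invert_erp

log = logging.getLogger("nmda_dcm")

#: latents estimated at the first level per experiment (others stay clamped)
CROSSOVER_FREE = (
    "blk_l", "blk_r", "ltau_ampa_l", "ltau_ampa_r", "ltau_gaba_l",
    "ltau_gaba_r", "ltau_nmda_l", "ltau_nmda_r", "b_l", "b_r",
)
DISEASE_FREE = ("blk_l", "blk_r", "b_l", "b_r")

#: the four parameter-set hypotheses; a fifth model frees them all
PARAMETER_SETS = {
    "gaba_tau": ("ltau_gaba_l", "ltau_gaba_r"),
    "ampa_tau": ("ltau_ampa_l", "ltau_ampa_r"),
    "nmda_tau": ("ltau_nmda_l", "ltau_nmda_r"),
    "nmda_blk": ("blk_l", "blk_r"),
}
BLOCKADE_FIELDS = ("blk_l", "blk_r")


def hypothesis_space() -> dict:
    hyp = {k: list(v) for k, v in PARAMETER_SETS.items()}
    hyp["all"] = [f for v in PARAMETER_SETS.values() for f in v]
    return hyp


@dataclass
class RunConfig:
    experiment: str = "crossover"       # crossover | severity | progression
    cohort: CohortSpec = field(default_factory=CohortSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    inversion: InversionSettings = field(default_factory=InversionSettings)
    peb: PEBSettings = field(default_factory=PEBSettings)
    seed: int = 0
    write_data: bool = True

    def __post_init__(self) -> None:
        if self.experiment not in ("crossover", "severity", "progression"):
            raise InvalidParameterError(f"unknown experiment {self.experiment!r}")
        kind = "crossover" if self.experiment == "crossover" else "longitudinal"
        if self.cohort.kind != kind:
            self.cohort = CohortSpec.from_dict({**self.cohort.to_dict(), "kind": kind})
        self.cohort = CohortSpec.from_dict({**self.cohort.to_dict(), "seed": self.seed})

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "cohort": self.cohort.to_dict(),
            "model": self.model.to_dict(),
            "inversion": asdict(self.inversion),
            "peb": asdict(self.peb),
            "seed": self.seed,
            "write_data": self.write_data,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "cohort" in kw:
            kw["cohort"] = CohortSpec.from_dict(kw["cohort"])
        if "model" in kw:
            kw["model"] = ModelConfig.from_dict(kw["model"])
        if "inversion" in kw:
            kw["inversion"] = InversionSettings(**kw["inversion"])
        if "peb" in kw:
            kw["peb"] = PEBSettings(**{k: tuple(v) if k == "gamma_bounds" else v
                                       for k, v in kw["peb"].items()})
        return cls(**kw)


def contrast_probability(result: PEBResult, names, weights=None) -> tuple[float, float]:
    """Posterior mean and sign probability of a linear contrast of beta."""
    idx = result.beta.index(names)
    w = np.asarray(weights if weights is not None else np.full(len(idx), 1.0 / len(idx)))
    mu = float(w @ result.beta.mean[idx])
    var = float(w @ result.beta.cov[np.ix_(idx, idx)] @ w)
    if var <= 0:
        return mu, 1.0
    return mu, float(norm.cdf(abs(mu) / np.sqrt(var)))


def interval_regressor(table: pd.DataFrame) -> np.ndarray:
    """Scan-interval column: 0 at baseline; follow-up years centred/standardised."""
    col = np.zeros(len(table))
    fup = (table["group"] == 1).to_numpy()
    if fup.any():
        iv = table.loc[fup, "interval_years"].to_numpy(dtype=float)
        sd = iv.std(ddof=0)
        col[fup] = (iv - iv.mean()) / sd if sd > 0 else 0.0
    return col


def sensor_stage(cohort: CohortData) -> dict:
    """Difference waveforms, windowed amplitudes, outliers-free group tests."""
    records = mmn_records(cohort.datasets)
    tab = amplitude_table(records)
    out = {"amplitudes": tab}
    sessions = sorted(tab["session"].unique())
    if len(sessions) == 2:
        first, second = ("baseline", "followup") if "baseline" in sessions \
            else ("placebo", "drug")
        a = tab[tab.session == first].set_index("subject")["amplitude"]
        b = tab[tab.session == second].set_index("subject")["amplitude"]
        shared = a.index.intersection(b.index)
        if len(shared) >= 2:
            tt = paired_t(b[shared].to_numpy(), a[shared].to_numpy())
            out["paired_t"] = {"t": tt.t, "p": tt.p, "dof": tt.dof,
                               "cohen_d": tt.cohen_d,
                               "contrast": f"{second} - {first}"}
    if tab["mmse"].notna().any() if "mmse" in tab else False:
        base = tab[tab.session == sessions[0]]
        reg = amplitude_vs_covariate(base["amplitude"].to_numpy(),
                                     base["mmse"].to_numpy())
        out["mmse_regression"] = {"slope": reg.slope, "r": reg.r, "p": reg.p}
    return out


def first_level_stage(cohort: CohortData, config: RunConfig, free) -> list:
    obs = default_observation(hanning=config.model.hanning)
    priors = default_priors(tuple(free))
    posteriors = []
    for k, ds in enumerate(cohort.datasets):
        t0 = time.time()
        res = invert_erp(ds, obs, config.model, priors, config.inversion)
        log.info("inverted %s/%s in %.2fs (F=%.1f, %d iter)",
                 ds.subject, ds.session, time.time() - t0, res.free_energy,
                 res.n_iter)
        posteriors.append(res)
    return posteriors


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Execute one experiment; returns (and optionally writes) the report."""
    t_start = time.time()
    timings = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    cohort = generate(config.cohort, config.model)
    timings["simulate"] = time.time() - t0
    if out_dir is not None and config.write_data:
        write_cohort(cohort, out_dir / "data")

    t0 = time.time()
    sensor = sensor_stage(cohort)
    timings["sensor_stats"] = time.time() - t0

    free = CROSSOVER_FREE if config.experiment == "crossover" else DISEASE_FREE
    t0 = time.time()
    results = first_level_stage(cohort, config, free)
    timings["invert"] = time.time() - t0
    if out_dir is not None:
        inv_dir = out_dir / "inversions"
        inv_dir.mkdir(exist_ok=True)
        for ds, res in zip(cohort.datasets, results):
            res.to_json(inv_dir / f"{ds.subject}_{ds.session}.json")

    t0 = time.time()
    posteriors = [r.posterior for r in results]
    table = cohort.table.copy()
    report = {
        "experiment": config.experiment,
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_recordings": len(cohort.datasets),
        "sensor": {k: v for k, v in sensor.items() if k != "amplitudes"},
        "first_level": {
            "converged": int(sum(r.converged for r in results)),
            "mean_iterations": float(np.mean([r.n_iter for r in results])),
        },
    }
    fl_priors = default_priors()

    if config.experiment == "crossover":
        design = PEBDesign.from_table(table, ["group"])
        fields = tuple(f for s in PARAMETER_SETS.values() for f in s)
        peb = fit_peb(posteriors, design, fields, fl_priors, config.peb,
                      row_index=table[["subject", "session"]])
        mc = model_space_compare(peb, hypothesis_space())
        bma, combos = all_combinations_bma(peb, PARAMETER_SETS)
        mu, prob = contrast_probability(peb, ["blk_l:group", "blk_r:group"])
        bma_mu = float(np.mean(bma.mean[bma.index(["blk_l:group", "blk_r:group"])]))
        report["model_comparison"] = mc.table.to_dict(orient="records")
        report["winning_model"] = mc.best
        report["drug_effect"] = {"blockade_mean": mu, "probability": prob,
                                 "bma_blockade_mean": bma_mu}
        report["effects"] = _effect_table(peb)
        extra_tables = {"model_probabilities": mc.table,
                        "bma_combinations": combos,
                        "subject_expectations": peb.subject_expectations}
    else:
        if config.experiment == "severity":
            table = table[table.session == "baseline"].reset_index(drop=True)
            posteriors = [p for p, row in zip(posteriors, cohort.table.itertuples())
                          if row.session == "baseline"]
            design = PEBDesign.from_table(table, ["mmse"], mean_center=["mmse"])
            effect_names = ["blk_l:mmse", "blk_r:mmse"]
        else:  # progression: completers only
            completers = table.groupby("subject")["session"].transform("nunique") == 2
            posteriors = [p for p, c in zip(posteriors, completers) if c]
            table = table[completers].reset_index(drop=True)
            table["interval_c"] = interval_regressor(table)
            design = PEBDesign.from_table(table, ["group", "interval_c"])
            effect_names = ["blk_l:group", "blk_r:group"]
        peb = fit_peb(posteriors, design, BLOCKADE_FIELDS, fl_priors, config.peb,
                      row_index=table[["subject", "session"]])
        bma, combos = all_combinations_bma(
            peb, {"nmda_blk": BLOCKADE_FIELDS})
        mu, prob = contrast_probability(peb, effect_names)
        report["blockade_effect"] = {
            "regressor": effect_names[0].split(":")[1],
            "mean": mu, "probability": prob,
            "bma_mean": float(np.mean(bma.mean[bma.index(effect_names)])),
        }
        report["effects"] = _effect_table(peb)
        extra_tables = {"bma_combinations": combos,
                        "subject_expectations": peb.subject_expectations}

    timings["peb"] = time.time() - t0
    timings["total"] = time.time() - t_start
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    if out_dir is not None:
        sensor["amplitudes"].to_csv(out_dir / "sensor_amplitudes.csv", index=False)
        for name, tab_ in extra_tables.items():
            tab_.to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _effect_table(peb: PEBResult) -> list:
    rows = []
    for i, name in enumerate(peb.beta.names):
        prob = peb.posterior_probability(name)
        rows.append({
            "effect": name,
            "estimate": float(peb.beta.mean[i]),
            "sd": float(np.sqrt(peb.beta.cov[i, i])),
            "probability": prob,
            "meaningful": bool(prob > 0.95),  # reporting flag, not a decision rule
        })
    return rows


def report_hash(report: dict) -> str:
    """Hash of the report with timing fields stripped (content identity)."""
    d = {k: v for k, v in report.items() if k != "timings_s"}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
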