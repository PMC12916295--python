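"""Synthetic cohorts with the statistical structure the analyses assume.

Two designs are generated, mirroring the studies the pipeline is built for:

* a placebo-controlled drug **crossover** in healthy adults (n = 19, two
  sessions two weeks apart) where the drug session shifts the NMDA-blockade
  latent upward (default +0.42);
* a **longitudinal** patient cohort (n = 42 at baseline, 30 completing a
  follow-up after 0.8-2.2 years) with an MMSE-linked blockade gradient
  (default 0.06 per MMSE point around the cohort mean), a blockade reduction
  at follow-up (default -0.125), and a weakening of the deviance modulation at
  follow-up that attenuates the sensor-level mismatch response.

Only the blockade latents vary across subjects by default (sd 0.125, matching
the prior); observation noise is IID Gaussian in windowed mode space.  Ground
truth is stored next to the data so recovery experiments can be scored
exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .erpio import ERPDataset, write_erp
from .errors import InvalidParameterError
from .forward import CONDITIONS, ObservationModel, default_observation, predict_evoked
from .params import MicrocircuitParameters, ModelConfig


@dataclass
class CohortSpec:
    """Design and effect sizes of one synthetic cohort."""

    kind: str = "crossover"            # "crossover" | "longitudinal"
    n_subjects: int = 19
    drug_shift: float = 0.42           # drug-session shift of both blockade latents
    mmse_slope: float = 0.06           # blockade per MMSE point (mean-centred)
    session_shift: float = -0.125      # follow-up shift of both blockade latents
    session_b_shift: float = 0.2       # follow-up weakening of the deviance modulation
    subject_sd: float = 0.125          # between-subject sd of the blockade latents
    noise_sd: float = 0.05             # sensor noise sd (mode space)
    true_b: float = -0.4               # deviance modulation common to all subjects
    mmse_mean: float = 24.9
    mmse_sd: float = 3.61
    mmse_range: tuple = (10.0, 30.0)
    interval_range: tuple = (0.8, 2.2)  # years between scans
    followup_fraction: float = 30.0 / 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("crossover", "longitudinal"):
            raise InvalidParameterError(f"unknown design kind {self.kind!r}")
        if self.n_subjects < 2:
            raise InvalidParameterError("need at least 2 subjects")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise sd must be strictly positive")
        if not 0.0 < self.followup_fraction <= 1.0:
            raise InvalidParameterError("follow-up fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mmse_range"] = list(self.mmse_range)
        d["interval_range"] = list(self.interval_range)
        return d

    @classmethod
    def from_dict(cls, d) -> "CohortSpec":
        d = dict(d)
        for k in ("mmse_range", "interval_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class CohortData(NamedTuple):
    datasets: list            # ERPDataset per subject/session
    table: pd.DataFrame       # covariates aligned with datasets
    truth: dict               # planted latents per subject/session


def _simulate_recording(config, obs, latents, rng, noise_sd, subject, session,
                        meta) -> ERPDataset:
    clean = predict_evoked(MicrocircuitParameters(config, latents), obs)
    noisy = clean + noise_sd * rng.standard_normal(clean.shape)
    return ERPDataset(
        subject, session, config.times(),
        {name: noisy[:, :, i] for i, name in enumerate(CONDITIONS)},
        meta=meta,
    )


def generate_crossover(spec: CohortSpec, config: ModelConfig | None = None,
                       obs: ObservationModel | None = None) -> CohortData:
    """Two sessions per subject; the drug session shifts both blockade latents."""
    config = config or ModelConfig()
    obs = obs or default_observation(hanning=config.hanning)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    datasets, rows, truth = [], [], {"spec": spec.to_dict(), "subjects": {}}
    for i in range(spec.n_subjects):
        sid = f"sub{i + 1:02d}"
        base = {
            "blk_l": rng.normal(0.0, spec.subject_sd),
            "blk_r": rng.normal(0.0, spec.subject_sd),
            "b_l": spec.true_b, "b_r": spec.true_b,
        }
        truth["subjects"][sid] = {}
        for session, on_drug in (("placebo", 0), ("drug", 1)):
            lat = dict(base)
            if on_drug:
                lat["blk_l"] += spec.drug_shift
                lat["blk_r"] += spec.drug_shift
            meta = {"group": on_drug, "design": "crossover"}
            datasets.append(_simulate_recording(
                config, obs, lat, rng, spec.noise_sd, sid, session, meta))
            rows.append({"subject": sid, "session": session, "group": on_drug,
                         "mmse": np.nan, "interval_years": 0.0})
            truth["subjects"][sid][session] = lat
    return CohortData(datasets, pd.DataFrame(rows), truth)


def generate_longitudinal(spec: CohortSpec, config: ModelConfig | None = None,
                          obs: ObservationModel | None = None) -> CohortData:
    """Baseline cohort with MMSE-linked blockade; a subset returns for follow-up."""
    config = config or ModelConfig()
    obs = obs or default_observation(hanning=config.hanning)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    lo, hi = spec.mmse_range
    a, b = (lo - spec.mmse_mean) / spec.mmse_sd, (hi - spec.mmse_mean) / spec.mmse_sd
    mmse = truncnorm.rvs(a, b, loc=spec.mmse_mean, scale=spec.mmse_sd,
                         size=spec.n_subjects, random_state=rng)
    n_followup = int(round(spec.followup_fraction * spec.n_subjects))
    datasets, rows, truth = [], [], {"spec": spec.to_dict(), "subjects": {}}
    for i in range(spec.n_subjects):
        sid = f"pat{i + 1:02d}"
        centred = mmse[i] - spec.mmse_mean
        base = {
            "blk_l": spec.mmse_slope * centred + rng.normal(0.0, spec.subject_sd),
            "blk_r": spec.mmse_slope * centred + rng.normal(0.0, spec.subject_sd),
            "b_l": spec.true_b, "b_r": spec.true_b,
        }
        interval = rng.uniform(*spec.interval_range)
        truth["subjects"][sid] = {}
        sessions = [("baseline", 0)]
        if i < n_followup:
            sessions.append(("followup", 1))
        for session, is_followup in sessions:
            lat = dict(base)
            if is_followup:
                lat["blk_l"] += spec.session_shift
                lat["blk_r"] += spec.session_shift
                lat["b_l"] += spec.session_b_shift
                lat["b_r"] += spec.session_b_shift
            meta = {"group": is_followup, "mmse": float(mmse[i]),
                    "interval_years": float(interval if is_followup else 0.0),
                    "design": "longitudinal"}
            datasets.append(_simulate_recording(
                config, obs, lat, rng, spec.noise_sd, sid, session, meta))
            rows.append({"subject": sid, "session": session, "group": is_followup,
                         "mmse": float(mmse[i]),
                         "interval_years": float(interval if is_followup else 0.0)})
            truth["subjects"][sid][session] = lat
    return CohortData(datasets, pd.DataFrame(rows), truth)


def generate(spec: CohortSpec, config: ModelConfig | None = None,
             obs: ObservationModel | None = None) -> CohortData:
    if spec.kind == "crossover":
        return generate_crossover(spec, config, obs)
    return generate_longitudinal(spec, config, obs)


def write_cohort(cohort: CohortData, directory) -> Path:
    """Write ERP files, the covariate CSV and the ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in cohort.datasets:
        write_erp(ds, directory)
    cohort.table.to_csv(directory / "covariates.csv", index=False)
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
    return directory


def read_cohort(directory) -> CohortData:
    """Read a cohort written by :func:`write_cohort`."""
    from .erpio import read_erp

    directory = Path(directory)
    table = pd.read_csv(directory / "covariates.csv")
    datasets = [read_erp(directory, row.subject, row.session)
                for row in table.itertuples()]
    with open(directory / "ground_truth.json") as fh:
        truth = json.load(fh)
    return CohortData(datasets, table, truth)
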