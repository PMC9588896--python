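"""Readers and writers for the package's CSV/JSON dialects."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .blrm import BLRMPrior, CohortRecord, EscalationRules, GridSpec, MtdRule, ToxicityIntervals
from .pkpd import BindingParams, PopulationSpec, Regimen, SimProfile, TwoCompartmentParams
from .trial import DesignConfig, ToxScenario

PathLike = Union[str, Path]

COHORT_COLUMNS = ["dose_mg", "n_patients", "n_dlt_patients"]


def read_cohorts_csv(path: PathLike) -> list[CohortRecord]:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        CohortRecord(float(r.dose_mg), int(r.n_patients), int(r.n_dlt_patients))
        for r in df.itertuples()
    ]


def write_cohorts_csv(cohorts, path: PathLike) -> None:
    pd.DataFrame(
        [(c.dose_mg, c.n_patients, c.n_dlt_patients) for c in cohorts],
        columns=COHORT_COLUMNS,
    ).to_csv(path, index=False)


def design_from_dict(cfg: dict) -> DesignConfig:
    prior = BLRMPrior(**cfg["prior"])
    rules = EscalationRules(**cfg["rules"])
    kwargs = dict(
        prior=prior,
        rules=rules,
        provisional_levels=tuple(cfg["provisional_levels"]),
        start_dose_mg=cfg["start_dose_mg"],
    )
    if "intervals" in cfg:
        kwargs["intervals"] = ToxicityIntervals(**cfg["intervals"])
    if "mtd_rule" in cfg:
        kwargs["mtd_rule"] = MtdRule(**cfg["mtd_rule"])
    if "grid_spec" in cfg:
        kwargs["grid_spec"] = GridSpec(**cfg["grid_spec"])
    for key in ("schedule", "cohort_size", "max_patients", "dlt_window_days", "expand_at_mtd"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return DesignConfig(**kwargs)


def read_design_json(path: PathLike) -> DesignConfig:
    with open(path) as fh:
        return design_from_dict(json.load(fh))


def read_scenario_json(path: PathLike) -> ToxScenario:
    with open(path) as fh:
        cfg = json.load(fh)
    return ToxScenario(tuple(cfg["doses_mg"]), tuple(cfg["dlt_probs"]))


def pkpd_config_from_dict(cfg: dict):
    """Returns (pk, ligands, regimen, population-or-None)."""
    pk = TwoCompartmentParams(**cfg["pk"])
    ligands = [BindingParams(**lig) for lig in cfg.get("ligands", [])]
    regimen = Regimen(**cfg["regimen"])
    pop = PopulationSpec(**cfg["population"]) if "population" in cfg else None
    return pk, ligands, regimen, pop


def read_pkpd_json(path: PathLike):
    with open(path) as fh:
        return pkpd_config_from_dict(json.load(fh))


def profile_to_long_frame(profile: SimProfile, subject: str = "S001") -> pd.DataFrame:
    """Long-format export: subject, time_days, variable, value."""
    rows = {"drug_central": profile.drug_central, "drug_peripheral": profile.drug_peripheral}
    for i, name in enumerate(profile.ligand_names or [f"ligand{i}" for i in range(len(profile.free_ligand))]):
        rows[f"free_{name}"] = profile.free_ligand[i]
        rows[f"complex_{name}"] = profile.complex[i]
        rows[f"total_{name}"] = profile.total_ligand(i)
    frames = []
    for var, vals in rows.items():
        frames.append(
            pd.DataFrame(
                dict(subject=subject, time_days=profile.times, variable=var, value=vals)
            )
        )
    return pd.concat(frames, ignore_index=True)
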