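"""Assemble a SurveyDataset from NHANES-style public-release files.

The adapter merges demographics, blood-pressure, household-smoking and
income files on the respondent ID, applies the eligibility and
complete-case filters in a fixed, logged order, and returns the analysis
dataset: children in the examined (MEC) subsample within a configurable age
window, outcome = mean of the available blood-pressure readings (mmHg),
exposure = any-household-smoker indicator, with the MEC exam weight and the
design (stratum/PSU) columns attached.

NHANES variable names change across cycles and live in each cycle's
codebook, so every column name is configuration (a :class:`NhanesMapping`,
loadable from YAML), never hard-coded. Files may be SAS transport (``.xpt``,
read via :func:`pandas.read_sas`) or CSV exports of the same tables.

This module only restructures user-supplied files; it downloads nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .survey_design import SurveyDataset

__all__ = ["NhanesMapping", "AdapterError", "build_analysis_dataset"]


class AdapterError(ValueError):
    """Missing variables or empty result while building the dataset."""


@dataclass
class NhanesMapping:
    """Column-name map for one NHANES cycle (user-editable configuration)."""

    id_col: str = "SEQN"
    age_col: str = "RIDAGEYR"
    sex_col: str = "RIAGENDR"
    ethnicity_col: str = "RIDRETH3"
    mec_weight_col: str = "WTMECPRP"
    stratum_col: str = "SDMVSTRA"
    psu_col: str = "SDMVPSU"
    sbp_cols: list[str] = field(
        default_factory=lambda: ["BPXOSY1", "BPXOSY2", "BPXOSY3"]
    )
    dbp_cols: list[str] = field(
        default_factory=lambda: ["BPXODI1", "BPXODI2", "BPXODI3"]
    )
    smoker_cols: list[str] = field(default_factory=lambda: ["SMD460"])
    # value(s) of the smoking variable(s) meaning "someone smokes in the home";
    # with multiple smoker_cols the exposure is 1 if ANY of them is positive
    smoker_positive_values: list[float] = field(default_factory=lambda: [1, 2, 3])
    income_col: str = "INDFMPIR"
    # poverty-to-income-ratio cutpoints -> {below, near, above} categories
    poverty_cutpoints: tuple[float, float] = (1.0, 2.0)
    age_range: tuple[float, float] = (8.0, 11.0)

    @classmethod
    def from_yaml(cls, path) -> "NhanesMapping":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("poverty_cutpoints", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".xpt":
        return pd.read_sas(path, format="xport")
    return pd.read_csv(path)


def _require(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise AdapterError(f"{table} file lacks mapped variable(s): {missing}")


def build_analysis_dataset(
    demographics_file,
    bp_file,
    smoking_file,
    income_file=None,
    mapping: NhanesMapping | None = None,
) -> tuple[SurveyDataset, dict[str, int]]:
    """Merge, filter and recode NHANES files into the analysis dataset.

    Exclusions are applied in a fixed order and each step's count recorded
    in the returned log: age eligibility, missing/zero exam weight, missing
    outcome, missing exposure. The counts sum to (merged rows - output
    rows). ``income_file`` may be None when the poverty variable already
    sits in the demographics file (as in recent cycles).
    """
    m = mapping or NhanesMapping()

    demo = _read_table(demographics_file)
    _require(
        demo,
        [m.id_col, m.age_col, m.sex_col, m.ethnicity_col, m.mec_weight_col],
        "demographics",
    )
    bp = _read_table(bp_file)
    _require(bp, [m.id_col], "blood pressure")
    present_sbp = [c for c in m.sbp_cols if c in bp.columns]
    if not present_sbp:
        raise AdapterError(f"blood pressure file lacks all SBP readings {m.sbp_cols}")
    present_dbp = [c for c in m.dbp_cols if c in bp.columns]
    smoke = _read_table(smoking_file)
    _require(smoke, [m.id_col] + m.smoker_cols, "smoking")

    df = demo.merge(bp, on=m.id_col, how="left").merge(
        smoke, on=m.id_col, how="left"
    )
    if income_file is not None:
        inc = _read_table(income_file)
        _require(inc, [m.id_col, m.income_col], "income")
        df = df.merge(inc[[m.id_col, m.income_col]], on=m.id_col, how="left")
    _require(df, [m.income_col], "merged")

    log: dict[str, int] = {}
    n0 = len(df)

    lo, hi = m.age_range
    eligible = df[m.age_col].between(lo, hi)
    log["age_ineligible"] = int((~eligible).sum())
    df = df[eligible]

    has_weight = df[m.mec_weight_col].notna() & (df[m.mec_weight_col] > 0)
    log["missing_exam_weight"] = int((~has_weight).sum())
    df = df[has_weight]

    sbp = df[present_sbp].mean(axis=1, skipna=True)
    has_outcome = sbp.notna()
    log["missing_outcome"] = int((~has_outcome).sum())
    df = df[has_outcome]
    sbp = sbp[has_outcome]

    pos = np.zeros(len(df), dtype=bool)
    seen = np.zeros(len(df), dtype=bool)
    for c in m.smoker_cols:
        col = df[c]
        seen |= col.notna().to_numpy()
        pos |= col.isin(m.smoker_positive_values).to_numpy()
    log["missing_exposure"] = int((~seen).sum())
    exposure = pos[seen]
    df = df[seen]

    if len(df) == 0:
        raise AdapterError("no rows remain after eligibility and missing-data filters")

    out = pd.DataFrame(
        {
            "id": df[m.id_col].to_numpy(),
            "Y": sbp.loc[df.index].to_numpy(dtype=float),
            "A": exposure.astype(int),
            "age": df[m.age_col].to_numpy(dtype=float),
            "sex": df[m.sex_col].to_numpy(),
            "eth": df[m.ethnicity_col].to_numpy(),
            "income": df[m.income_col].to_numpy(dtype=float),
            "weight": df[m.mec_weight_col].to_numpy(dtype=float),
        }
    )
    if present_dbp:
        out["Y_dbp"] = df[present_dbp].mean(axis=1, skipna=True).to_numpy()
    below, near = m.poverty_cutpoints
    out["poverty_cat"] = pd.cut(
        out["income"],
        bins=[-np.inf, below, near, np.inf],
        labels=["below", "near", "above"],
    )
    stratum = psu = None
    if m.stratum_col in df.columns and m.psu_col in df.columns:
        # PSU codes repeat across strata in NHANES files; combine for uniqueness
        out["stratum"] = df[m.stratum_col].to_numpy()
        out["psu"] = [
            f"{s}-{p}"
            for s, p in zip(df[m.stratum_col].to_numpy(), df[m.psu_col].to_numpy())
        ]
        stratum, psu = "stratum", "psu"

    dataset = SurveyDataset(
        data=out.reset_index(drop=True),
        outcome="Y",
        exposure="A",
        weight="weight",
        stratum=stratum,
        psu=psu,
    )
    assert sum(log.values()) == n0 - len(out)
    return dataset, log
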