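"""Synthetic hospital and encounter generator with recorded ground truth.

Real analyses of interhospital transfer in emergency general surgery (EGS) run
on licensed all-payer claims (state inpatient and ED discharge databases joined
to hospital surveys). This module emulates the *statistical structure* those
analyses assume, at desk scale, with every latent quantity recorded so that
downstream stages can be tested by parameter recovery:

* hospitals carry a latent ``resource_score`` (attractiveness for incoming
  transfers) and ``quality_effect`` (additive log-odds shift on death and
  complication at the treating hospital);
* a transferred patient produces an origin encounter (ED-only or inpatient) at
  hospital A and an inpatient encounter at hospital B != A whose admission date
  is the same day or the day after the origin discharge — exactly the temporal
  adjacency the linkage stage looks for;
* the transfer destination is drawn with probability proportional to
  ``exp(destination_preference_strength * resource_score)``;
* death and complication are Bernoulli draws from logistic models in age, sex,
  comorbidity index and the treating hospital's quality effect.

All randomness flows from a single seed through named substreams, so each
table is bit-reproducible and stages can be regenerated independently.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from math import log
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .codes import CodeSet, ComorbidityMap, default_codeset, default_comorbidity_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_hospitals",
    "generate_encounters",
    "simulate",
]

#: The eight study states of the claims sample the generator emulates.
DEFAULT_STATES = ("AR", "FL", "MA", "MD", "NE", "NY", "VT", "WI")

# Diagnosis filler for non-EGS inpatient stays and ED presenting complaints.
_NON_EGS_DX = ("E119", "I10", "J449X", "N390", "I5030")
_ED_SYMPTOM_DX = ("R1031", "R109", "R112", "R509", "R0789")

_YEAR_START = _dt.date(2016, 1, 1)


def logit(p: float) -> float:
    return log(p / (1.0 - p))


class SimulationConfig(BaseModel):
    """Knobs of the synthetic claims world.

    Defaults are chosen to resemble a one-year, multi-state EGS claims sample
    at desk scale: overall in-hospital mortality near 5% (baseline 1.8% at the
    covariate reference, rising with age, male sex, comorbidity burden and a
    post-complication shift), failure to rescue near 12%, roughly 40% of
    inpatient encounters involving an operation, and slightly more than half
    of transfers originating in the ED.
    """

    model_config = {"frozen": True}

    n_hospitals: int = Field(default=150, ge=2)
    n_patients: int = Field(default=40_000, ge=1)
    states: tuple[str, ...] = DEFAULT_STATES

    egs_probability: float = Field(default=0.7, ge=0.0, le=1.0)
    transfer_probability: float = Field(default=0.3, ge=0.0, le=1.0)
    chain_probability: float = Field(default=0.05, ge=0.0, le=1.0)
    non_admitted_probability: float = Field(default=0.1, ge=0.0, le=1.0)
    minor_probability: float = Field(default=0.03, ge=0.0, le=1.0)
    ed_origin_probability: float = Field(default=0.55, ge=0.0, le=1.0)
    operation_probability: float = Field(default=0.4, ge=0.0, le=1.0)
    comorbidity_prevalence: float = Field(default=0.08, ge=0.0, le=1.0)

    destination_preference_strength: float = Field(default=1.0, ge=0.0)
    quality_effect_scale: float = Field(default=0.3, ge=0.0)

    baseline_death_logodds: float = logit(0.018)
    baseline_complication_logodds: float = logit(0.12)
    age_effect: float = 0.03
    sex_effect: float = 0.1
    comorbidity_effect: float = 0.1
    #: extra death log-odds when a complication occurred (drives failure to rescue)
    complication_death_boost: float = 0.8

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.states:
            raise ValueError("states: at least one state is required")
        if not np.isfinite(self.destination_preference_strength):
            raise ValueError("destination_preference_strength: must be finite")
        return self


@dataclass
class GroundTruth:
    """Latent truths recorded during generation, for recovery testing."""

    hospitals: pd.DataFrame  # hospital_id, resource_score, quality_effect, ...
    coefficients: dict  # patient-level model coefficients actually used
    planted_transfers: pd.DataFrame  # adult-EGS-cohort transfers the linker must find
    transfer_counts: pd.DataFrame  # origin, destination, count (aggregated)
    planted_volume: pd.Series  # per-hospital untransferred adult EGS inpatient episodes
    patients: pd.DataFrame  # per-patient latent state (treating hospital, flags, index)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "coefficients": self.coefficients,
            "hospitals": {
                row.hospital_id: {
                    "resource_score": float(row.resource_score),
                    "quality_effect": float(row.quality_effect),
                }
                for row in self.hospitals.itertuples()
            },
            "transfer_counts": [
                {"origin": o, "destination": d, "count": int(c)}
                for o, d, c in self.transfer_counts.itertuples(index=False)
            ],
            "planted_volume": {k: int(v) for k, v in self.planted_volume.items()},
            "n_planted_transfers": int(len(self.planted_transfers)),
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream: independent generator per stage under one seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _ensure_level_coverage(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Force every categorical level to appear when there is room (n >= 12).

    Random draws can miss rare levels (level-1 trauma, large teaching) in small
    tables; downstream contrasts need every level observed. The largest
    hospitals are deterministically promoted into any missing high-resource
    level, the smallest into missing low-resource levels.
    """
    if len(df) < 12:
        return df
    by_size = df.sort_values("total_beds", ascending=False).index
    specs = [
        ("teaching_status", ["large", "small", "nonteaching"]),
        ("trauma_level", ["1", "2", "3", "none"]),
    ]
    for col, levels_by_resource in specs:
        for rank, level in enumerate(levels_by_resource):
            if level not in set(df[col]):
                # promote the rank-th largest (or smallest for low-resource levels)
                idx = by_size[rank] if rank < 2 else by_size[-(rank - 1)]
                df.loc[idx, col] = level
    if df["fellowship"].nunique() < 2:
        df.loc[by_size[0], "fellowship"] = True
        df.loc[by_size[-1], "fellowship"] = False
    return df


def generate_hospitals(config: SimulationConfig) -> pd.DataFrame:
    """Generate the hospital attribute table.

    Returns a DataFrame with columns ``hospital_id, state, total_beds,
    icu_beds, teaching_status, trauma_level, fellowship, resource_score,
    quality_effect``. ``resource_score`` is built from (standardised log) bed
    and ICU counts plus noise, so it is positively correlated with size and
    ICU capacity by construction.
    """
    rng = _rng(config.seed, 1)
    n = config.n_hospitals

    hospital_id = np.array([f"H{i:04d}" for i in range(1, n + 1)])
    states = list(config.states)[: max(1, min(len(config.states), n))]
    state = np.array(
        states + list(rng.choice(states, size=n - len(states))) if n > len(states) else states[:n]
    )

    total_beds = np.clip(np.round(np.exp(rng.normal(4.8, 0.8, n))).astype(int), 10, 1500)
    icu_frac = rng.beta(2.0, 16.0, n)
    icu_beds = np.minimum(total_beds, np.round(total_beds * icu_frac).astype(int))

    size_score = np.log(total_beds) + rng.normal(0.0, 0.5, n)
    teaching = np.where(size_score > np.log(500), "large",
                        np.where(size_score > np.log(200), "small", "nonteaching"))
    trauma_score = np.log(total_beds) + rng.normal(0.0, 0.6, n)
    trauma = np.where(trauma_score > np.log(600), "1",
                      np.where(trauma_score > np.log(350), "2",
                               np.where(trauma_score > np.log(180), "3", "none")))
    fellowship = rng.random(n) < 1.0 / (1.0 + np.exp(-(size_score - np.log(600))))

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    resource_score = (
        0.6 * _z(np.log(total_beds))
        + 0.4 * _z(np.log1p(icu_beds))
        + rng.normal(0.0, 0.3, n)
    )
    quality_effect = rng.uniform(-config.quality_effect_scale, config.quality_effect_scale, n)

    df = pd.DataFrame(
        {
            "hospital_id": hospital_id,
            "state": state,
            "total_beds": total_beds,
            "icu_beds": icu_beds,
            "teaching_status": teaching,
            "trauma_level": trauma,
            "fellowship": fellowship,
            "resource_score": resource_score,
            "quality_effect": quality_effect,
        }
    )
    return _ensure_level_coverage(df, rng)


def _gumbel_choice(
    rng: np.random.Generator, logits: np.ndarray, forbidden: np.ndarray
) -> np.ndarray:
    """Row-wise categorical draw via the Gumbel-max trick, masking one column per row."""
    m = forbidden.shape[0]
    scores = logits[None, :] + rng.gumbel(size=(m, logits.size))
    scores[np.arange(m), forbidden] = -np.inf
    return scores.argmax(axis=1)


def generate_encounters(
    hospitals: pd.DataFrame,
    config: SimulationConfig,
    codes: CodeSet | None = None,
    comorbidity: ComorbidityMap | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the encounter table and its ground truth.

    Every patient contributes one episode: an ED-only visit, a single
    inpatient stay, or a transfer chain (origin -> destination [-> second
    destination]). Encounters of one chain are temporally adjacent across
    hospitals by construction; no other cross-hospital adjacency exists, so
    the planted transfer list is exactly what a correct linker must recover.
    """
    if hospitals.empty:
        raise ValueError("hospitals: table must be non-empty")
    codes = codes or default_codeset()
    comorbidity = comorbidity or default_comorbidity_map()
    rng = _rng(config.seed, 2)
    n = config.n_patients
    H = len(hospitals)

    hosp_ids = hospitals["hospital_id"].to_numpy()
    hosp_state = hospitals["state"].to_numpy()
    resource = hospitals["resource_score"].to_numpy(dtype=float)
    quality = hospitals["quality_effect"].to_numpy(dtype=float)

    # ---- patient-level draws -------------------------------------------------
    patient_id = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    minor = rng.random(n) < config.minor_probability
    age = np.where(minor, rng.integers(1, 18, n), rng.integers(18, 96, n))
    sex = np.where(rng.random(n) < 0.521, "M", "F")

    com_cats = comorbidity.categories
    com_weights = np.array([comorbidity.weights[c] for c in com_cats], dtype=float)
    com_flags = rng.random((n, len(com_cats))) < config.comorbidity_prevalence
    com_index = (com_flags @ com_weights).astype(int)

    non_admitted = rng.random(n) < config.non_admitted_probability
    egs = ~non_admitted & (rng.random(n) < config.egs_probability)
    transferred = ~non_admitted & (rng.random(n) < config.transfer_probability)
    origin_idx = rng.integers(0, H, n)
    origin_is_ed = transferred & (rng.random(n) < config.ed_origin_probability)

    # transfer destinations: softmax(strength * resource), origin excluded
    logits = config.destination_preference_strength * resource
    t_rows = np.flatnonzero(transferred)
    dest_idx = np.full(n, -1)
    if t_rows.size:
        dest_idx[t_rows] = _gumbel_choice(rng, logits, origin_idx[t_rows])
    chain = transferred & (rng.random(n) < config.chain_probability)
    c_rows = np.flatnonzero(chain)
    chain_idx = np.full(n, -1)
    if c_rows.size:
        chain_idx[c_rows] = _gumbel_choice(rng, logits, dest_idx[c_rows])

    treat_idx = np.where(chain, chain_idx, np.where(transferred, dest_idx, origin_idx))

    # ---- dates (integer day offsets within the study year) ------------------
    admit0 = rng.integers(0, 300, n)
    ip_los = lambda size: np.minimum(rng.geometric(0.3, size) - 1, 25)  # noqa: E731
    los0 = np.where(non_admitted | origin_is_ed, 0, ip_los(n))
    disc0 = admit0 + los0
    # a zero-day upstream stay with a same-day transfer would tie the two
    # admission dates, which no date-resolution linker can order; force the
    # next-day variant of the adjacency rule in that case
    gap1 = np.where(los0 == 0, 1, rng.integers(0, 2, n))
    admit1 = disc0 + gap1
    los1 = ip_los(n)
    disc1 = admit1 + los1
    gap2 = np.where(los1 == 0, 1, rng.integers(0, 2, n))
    admit2 = disc1 + gap2
    disc2 = admit2 + ip_los(n)

    # ---- operations ----------------------------------------------------------
    op_pool = sorted(codes.operation_proc)
    draw_op = lambda size: rng.random(size) < config.operation_probability  # noqa: E731
    op0 = draw_op(n) & ~non_admitted & ~origin_is_ed  # inpatient encounters only
    op1 = draw_op(n) & transferred
    op2 = draw_op(n) & chain
    op_code = rng.integers(0, len(op_pool), (n, 3))
    operated = op0 | op1 | op2

    # ---- complication & death (logistic, treating-hospital quality) ---------
    is_inpatient_episode = ~non_admitted
    lin = (
        config.age_effect * (age - 60.0)
        + config.sex_effect * (sex == "M")
        + config.comorbidity_effect * com_index
        + quality[treat_idx]
    )
    p_comp = 1.0 / (1.0 + np.exp(-(config.baseline_complication_logodds + lin)))
    complication = is_inpatient_episode & (rng.random(n) < p_comp)
    p_death = 1.0 / (
        1.0
        + np.exp(
            -(
                config.baseline_death_logodds
                + lin
                + config.complication_death_boost * complication
            )
        )
    )
    died = is_inpatient_episode & (rng.random(n) < p_death)

    # ---- diagnosis code assembly --------------------------------------------
    egs_cats = sorted(codes.egs_dx_categories)
    egs_cat_codes = [sorted(codes.egs_dx_categories[c]) for c in egs_cats]
    egs_cat_idx = rng.integers(0, len(egs_cats), n)
    egs_code_pick = rng.random(n)
    comp_pool = sorted(codes.complication_dx)
    comp_pick = rng.integers(0, len(comp_pool), n)
    filler_pick = rng.integers(0, len(_NON_EGS_DX), n)
    symptom_pick = rng.integers(0, len(_ED_SYMPTOM_DX), n)

    com_code_lists: list[list[str]] = []
    cat_first_code = {c: sorted(codes_)[0] for c, codes_ in zip(com_cats, [
        [code for code, cat in comorbidity.category_map.items() if cat == c] for c in com_cats
    ])}
    for i in range(n):
        flags = com_flags[i]
        com_code_lists.append([cat_first_code[com_cats[k]] for k in np.flatnonzero(flags)])

    def _egs_code(i: int) -> str:
        pool = egs_cat_codes[egs_cat_idx[i]]
        return pool[int(egs_code_pick[i] * len(pool))]

    def _ip_dx(i: int, treating: bool) -> str:
        dx = []
        if egs[i]:
            dx.append(_egs_code(i))
        else:
            dx.append(_NON_EGS_DX[filler_pick[i]])
        dx.extend(com_code_lists[i])
        if treating and complication[i]:
            dx.append(comp_pool[comp_pick[i]])
        return ";".join(dx)

    # ---- encounter rows ------------------------------------------------------
    rows: dict[str, list] = {k: [] for k in (
        "patient_id", "hospital_id", "state", "setting", "admit_day", "discharge_day",
        "age", "sex", "dx_codes", "proc_codes", "died",
    )}

    def _emit(i, h, setting, a, d, dx, proc, dead):
        rows["patient_id"].append(patient_id[i])
        rows["hospital_id"].append(hosp_ids[h])
        rows["state"].append(hosp_state[h])
        rows["setting"].append(setting)
        rows["admit_day"].append(a)
        rows["discharge_day"].append(d)
        rows["age"].append(age[i])
        rows["sex"].append(sex[i])
        rows["dx_codes"].append(dx)
        rows["proc_codes"].append(proc)
        rows["died"].append(int(dead))

    for i in range(n):
        if non_admitted[i]:
            _emit(i, origin_idx[i], "ED", admit0[i], disc0[i],
                  _ED_SYMPTOM_DX[symptom_pick[i]], "", False)
            continue
        treating0 = not transferred[i]
        if origin_is_ed[i]:
            _emit(i, origin_idx[i], "ED", admit0[i], disc0[i],
                  _ED_SYMPTOM_DX[symptom_pick[i]] + ";" + ";".join(com_code_lists[i]) if com_code_lists[i] else _ED_SYMPTOM_DX[symptom_pick[i]],
                  "", False)
        else:
            _emit(i, origin_idx[i], "IP", admit0[i], disc0[i], _ip_dx(i, treating0),
                  op_pool[op_code[i, 0]] if op0[i] else "",
                  died[i] and treating0)
        if transferred[i]:
            treating1 = not chain[i]
            _emit(i, dest_idx[i], "IP", admit1[i], disc1[i], _ip_dx(i, treating1),
                  op_pool[op_code[i, 1]] if op1[i] else "",
                  died[i] and treating1)
        if chain[i]:
            _emit(i, chain_idx[i], "IP", admit2[i], disc2[i], _ip_dx(i, True),
                  op_pool[op_code[i, 2]] if op2[i] else "",
                  died[i])

    enc = pd.DataFrame(rows)
    base = pd.Timestamp(_YEAR_START)
    enc["admit_date"] = base + pd.to_timedelta(enc.pop("admit_day"), unit="D")
    enc["discharge_date"] = base + pd.to_timedelta(enc.pop("discharge_day"), unit="D")
    enc = enc[
        ["patient_id", "hospital_id", "state", "setting", "admit_date", "discharge_date",
         "age", "sex", "dx_codes", "proc_codes", "died"]
    ]

    # ---- ground truth --------------------------------------------------------
    cohort = transferred & egs & (age >= 18)
    pt_rows = []
    for i in np.flatnonzero(cohort):
        pt_rows.append(
            (patient_id[i], hosp_ids[origin_idx[i]], hosp_ids[dest_idx[i]],
             "ED->IP" if origin_is_ed[i] else "IP->IP", bool(op0[i] or op1[i]))
        )
        if chain[i]:
            pt_rows.append(
                (patient_id[i], hosp_ids[dest_idx[i]], hosp_ids[chain_idx[i]],
                 "IP->IP", bool(op1[i] or op2[i]))
            )
    planted = pd.DataFrame(
        pt_rows,
        columns=["patient_id", "origin_hospital", "destination_hospital",
                 "transfer_type", "any_operation"],
    )
    counts = (
        planted.groupby(["origin_hospital", "destination_hospital"], as_index=False)
        .size().rename(columns={"size": "count",
                                "origin_hospital": "origin",
                                "destination_hospital": "destination"})
        if len(planted)
        else pd.DataFrame(columns=["origin", "destination", "count"])
    )
    vol_mask = egs & ~transferred & ~non_admitted & (age >= 18)
    planted_volume = (
        pd.Series(hosp_ids[origin_idx[vol_mask]]).value_counts()
        .reindex(hosp_ids, fill_value=0).sort_index()
    )
    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "treating_hospital": hosp_ids[treat_idx],
            "age": age,
            "sex": sex,
            "comorbidity_index": com_index,
            "egs": egs,
            "inpatient": is_inpatient_episode,
            "transferred": transferred,
            "operated": operated & is_inpatient_episode,
            "complication": complication,
            "died": died,
        }
    )
    truth = GroundTruth(
        hospitals=hospitals,
        coefficients={
            "baseline_death_logodds": config.baseline_death_logodds,
            "baseline_complication_logodds": config.baseline_complication_logodds,
            "age_effect": config.age_effect,
            "sex_effect": config.sex_effect,
            "comorbidity_effect": config.comorbidity_effect,
            "complication_death_boost": config.complication_death_boost,
            "age_centering": 60.0,
        },
        planted_transfers=planted,
        transfer_counts=counts,
        planted_volume=planted_volume,
        patients=patients,
    )
    return enc, truth


def simulate(
    config: SimulationConfig,
    codes: CodeSet | None = None,
    comorbidity: ComorbidityMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: hospitals + encounters + ground truth in one call."""
    hospitals = generate_hospitals(config)
    encounters, truth = generate_encounters(hospitals, config, codes, comorbidity)
    return hospitals, encounters, truth
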