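"""Hospital EGS volume, risk-adjusted outcomes, and quartile categorisation.

Hospital performance is profiled on all adult EGS inpatient episodes (whether
or not they involved a transfer):

* **EGS volume** — number of EGS inpatient episodes treated at the hospital
  that did not result in a transfer within the year.
* **Risk-adjusted in-hospital mortality** — indirect standardisation: a
  patient-level logistic model of death in age, sex, comorbidity index and
  EGS diagnosis-category indicators is fitted on the pooled population; each
  hospital's rate is (observed / expected) x overall rate. Whether the
  patient received an operation is deliberately *not* adjusted for, as it is
  potentially endogenous to hospital quality.
* **Risk-adjusted failure to rescue (FTR)** — the same standardisation for
  death among operated episodes that developed a complication; nonoperatively
  managed episodes are out of scope and operated episodes without a
  complication fall outside the denominator.

Outcomes of transferred episodes are attributed to the treating (final
inpatient) hospital. Note this inherits the usual discharge-bias caveat of
claims-based profiling: hospitals that transfer out patients likely to die
look artificially good.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .codes import CodeSet, ComorbidityMap, normalize_code
from .linkage import Episode

__all__ = [
    "FTRStatus",
    "comorbidity_index",
    "flag_failure_to_rescue",
    "episode_table",
    "compute_egs_volume",
    "EpisodeRiskModel",
    "EpisodeRiskResults",
    "RiskModelError",
    "indirect_standardized_rate",
    "hospital_adjusted_rates",
    "assign_quartiles",
    "hospital_outcomes_table",
]

logger = logging.getLogger(__name__)


class RiskModelError(RuntimeError):
    """Raised when the episode-level risk model cannot be fitted."""


class FTRStatus(enum.Enum):
    """Failure-to-rescue classification of one episode."""

    NOT_APPLICABLE = "not_applicable"  # no operation/procedure in the episode
    NO_COMPLICATION = "no_complication"  # operated, outside the FTR denominator
    SURVIVED = "survived"  # operated, complication, lived
    DIED = "died"  # operated, complication, in-hospital death


def comorbidity_index(
    dx_codes: Iterable[str],
    weight_table: Mapping[str, int],
    category_map: Mapping[str, str],
) -> int:
    """Weighted comorbidity score: sum of weights over *distinct* categories.

    Codes that map to no category contribute nothing; multiple codes in one
    category count the category once.
    """
    cats = {
        category_map[c]
        for c in (normalize_code(x) for x in dx_codes)
        if c in category_map
    }
    return sum(int(weight_table[c]) for c in cats)


def flag_failure_to_rescue(episode: Episode, codes: CodeSet) -> FTRStatus:
    """Classify an episode for the failure-to-rescue measure."""
    operated = any(e.proc_codes & codes.operation_proc for e in episode.encounters)
    if not operated:
        return FTRStatus.NOT_APPLICABLE
    complication = bool(episode.all_dx() & codes.complication_dx)
    if not complication:
        return FTRStatus.NO_COMPLICATION
    return FTRStatus.DIED if episode.died else FTRStatus.SURVIVED


def episode_table(
    episodes: Iterable[Episode],
    codes: CodeSet,
    comorbidity: ComorbidityMap,
    min_age: int = 18,
) -> pd.DataFrame:
    """One row per adult EGS inpatient episode, ready for risk modelling."""
    rows = []
    for ep in episodes:
        if not (ep.egs and ep.inpatient and ep.age_at_first >= min_age):
            continue
        ftr = flag_failure_to_rescue(ep, codes)
        rows.append(
            {
                "patient_id": ep.patient_id,
                "hospital_id": ep.treating_hospital,
                "state": next(
                    (e.state for e in reversed(ep.encounters) if e.setting == "IP"),
                    ep.encounters[-1].state,
                ),
                "age": ep.age_at_first,
                "sex": ep.encounters[0].sex,
                "comorbidity_index": comorbidity_index(
                    ep.all_dx(), comorbidity.weights, comorbidity.category_map
                ),
                "egs_category": ep.egs_category or "unclassified",
                "transferred": ep.transferred,
                "n_transfers": len(ep.transfer_events),
                "operated": ftr is not FTRStatus.NOT_APPLICABLE,
                "complication": ftr in (FTRStatus.SURVIVED, FTRStatus.DIED),
                "died": ep.died,
                "ftr_status": ftr.value,
            }
        )
    return pd.DataFrame(rows)


def compute_egs_volume(episode_frame: pd.DataFrame) -> pd.Series:
    """Per-hospital EGS volume: untransferred EGS inpatient episodes treated there."""
    if episode_frame.empty:
        return pd.Series(dtype=int, name="egs_volume")
    keep = episode_frame[~episode_frame["transferred"].astype(bool)]
    vol = keep.groupby("hospital_id").size()
    vol = vol.reindex(sorted(episode_frame["hospital_id"].unique()), fill_value=0)
    vol.name = "egs_volume"
    return vol


class EpisodeRiskModel:
    """Patient-level logistic risk model for in-hospital death or FTR.

    Statsmodels-style: construct from an episode table, then :meth:`fit`.

    Parameters
    ----------
    episode_frame : output of :func:`episode_table`.
    outcome : ``"death"`` (all EGS inpatient episodes) or ``"ftr"``
        (operated episodes with a complication; outcome = in-hospital death).
    min_episodes : minimum eligible episodes required to fit (default 50).
    """

    def __init__(
        self,
        episode_frame: pd.DataFrame,
        outcome: str = "death",
        min_episodes: int = 50,
    ) -> None:
        if outcome not in ("death", "ftr"):
            raise ValueError(f"unknown outcome {outcome!r}; expected 'death' or 'ftr'")
        self.outcome = outcome
        if outcome == "death":
            eligible = episode_frame.copy()
        else:
            eligible = episode_frame[
                episode_frame["ftr_status"].isin(["survived", "died"])
            ].copy()
        eligible["y"] = eligible["died"].astype(int)
        self.frame = eligible.reset_index(drop=True)
        if len(self.frame) < min_episodes:
            raise RiskModelError(
                f"{outcome}: only {len(self.frame)} eligible episodes (< {min_episodes})"
            )
        if self.frame["y"].nunique() < 2:
            raise RiskModelError(f"{outcome}: outcome has a single class; cannot fit")
        # constant covariates and single-level factors are dropped so a
        # degenerate population collapses cleanly to the intercept-only model
        terms = []
        if self.frame["age"].nunique() > 1:
            terms.append("age")
        if self.frame["sex"].nunique() > 1:
            terms.append("C(sex)")
        if self.frame["comorbidity_index"].nunique() > 1:
            terms.append("comorbidity_index")
        if self.frame["egs_category"].nunique() > 1:
            terms.append("C(egs_category)")
        self.formula = "y ~ " + (" + ".join(terms) if terms else "1")

    def fit(self) -> "EpisodeRiskResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = smf.logit(self.formula, data=self.frame).fit(disp=0, maxiter=200)
            except Exception as exc:  # perfect separation, singular matrix, ...
                raise RiskModelError(
                    f"{self.outcome}: logistic fit failed ({exc}); check for "
                    "complete separation or collinear adjusters"
                ) from exc
        if not np.all(np.isfinite(res.params)):
            raise RiskModelError(f"{self.outcome}: non-finite coefficients (separation?)")
        return EpisodeRiskResults(self, res)


@dataclass
class EpisodeRiskResults:
    """Fitted risk model: coefficients, predictions, and the pooled rate."""

    model: EpisodeRiskModel
    _res: object  # statsmodels LogitResults

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def overall_rate(self) -> float:
        return float(self.model.frame["y"].mean())

    def predicted(self) -> np.ndarray:
        """Per-episode expected event probability on the fitted population."""
        return np.asarray(self._res.predict(self.model.frame))

    def summary(self):
        return self._res.summary()

    def coefficients(self) -> dict[str, float]:
        return {k: float(v) for k, v in self._res.params.items()}


def indirect_standardized_rate(observed: float, expected: float, overall_rate: float) -> float:
    """Indirect standardisation: (observed / expected events) x overall rate."""
    if expected <= 0:
        return float("nan")
    return observed / expected * overall_rate


def hospital_adjusted_rates(results: EpisodeRiskResults) -> pd.Series:
    """Indirectly standardised per-hospital rate: (O / E) x overall rate.

    Hospitals with no eligible episodes are absent; a hospital whose expected
    count is zero while events were observed yields NaN with a warning (cannot
    occur for a fitted logistic model, whose predictions are strictly
    positive, but guarded for replaceable model backends).
    """
    frame = results.model.frame
    pred = results.predicted()
    df = pd.DataFrame(
        {"hospital_id": frame["hospital_id"], "obs": frame["y"], "exp": pred}
    )
    agg = df.groupby("hospital_id").sum()
    rate = np.where(
        agg["exp"] > 0, agg["obs"] / agg["exp"] * results.overall_rate, np.nan
    )
    bad = (agg["exp"] <= 0) & (agg["obs"] > 0)
    if bad.any():
        logger.warning(
            "adjusted rate undefined for %d hospital(s): expected events = 0 "
            "with observed > 0", int(bad.sum()),
        )
    out = pd.Series(rate, index=agg.index, name=f"adj_{results.model.outcome}")
    return out.sort_index()


def assign_quartiles(values: pd.Series) -> pd.Series:
    """Quartile labels 1-4 (1 = lowest) with ties assigned downward.

    Cut points are the empirical 25th/50th/75th percentiles of the *defined*
    values; values equal to a cut point fall in the lower quartile. Undefined
    (NaN) entries receive no label. Fewer than 4 defined values is an error.
    """
    v = values.astype(float)
    defined = v.dropna()
    if len(defined) < 4:
        raise ValueError(f"need >= 4 defined values to form quartiles, got {len(defined)}")
    q25, q50, q75 = np.percentile(defined, [25, 50, 75])
    if q25 == q75:
        warnings.warn("all quartile cut points coincide; assigning quartile 1 to ties")
    labels = 1 + (v > q25).astype(int) + (v > q50).astype(int) + (v > q75).astype(int)
    return labels.where(v.notna()).astype("Int64")


def hospital_outcomes_table(
    episode_frame: pd.DataFrame,
    mortality: EpisodeRiskResults,
    ftr: EpisodeRiskResults | None,
) -> pd.DataFrame:
    """Hospital-level volume, adjusted rates, and quartile labels."""
    vol = compute_egs_volume(episode_frame)
    adj_mort = hospital_adjusted_rates(mortality)
    out = pd.DataFrame({"egs_volume": vol})
    out["adj_mortality"] = adj_mort
    if ftr is not None:
        out["adj_ftr"] = hospital_adjusted_rates(ftr)
    else:
        out["adj_ftr"] = np.nan
    out["volume_quartile"] = assign_quartiles(out["egs_volume"])
    out["mortality_quartile"] = assign_quartiles(out["adj_mortality"])
    try:
        out["ftr_quartile"] = assign_quartiles(out["adj_ftr"])
    except ValueError:
        out["ftr_quartile"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out.index.name = "hospital_id"
    return out.reset_index()
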