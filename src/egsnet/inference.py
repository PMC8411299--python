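"""Association of the log centrality ratio with hospital characteristics.

Two layers, mirroring standard health-services practice:

* **One-way ANOVA with post hoc pairwise contrasts** of the log-transformed
  centrality ratio across each hospital characteristic separately (Tukey HSD
  by default; unadjusted and Bonferroni pairwise t tests are available).
* **Multivariable OLS** of the log ratio on all characteristic blocks at once
  (bed category, ICU-bed category, trauma level, fellowship, teaching status,
  and quartiles of EGS volume, mortality, failure to rescue), with
  cluster-robust (sandwich) standard errors clustered on state and a partial
  F (Wald) test per block. With few clusters the asymptotic sandwich is
  fragile, so inference uses the t distribution with G - 1 degrees of freedom
  and the usual finite-sample scaling G/(G-1) x (n-1)/(n-k).

The model/results split follows statsmodels: build a
:class:`CentralityAssociationModel` from an analysis frame, call ``fit()``,
and read estimates, intervals and the partial-F table off the results object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DEFAULT_BLOCKS",
    "RESOURCE_BLOCKS",
    "AnovaResult",
    "build_analysis_frame",
    "anova_with_pairwise",
    "CentralityAssociationModel",
    "CentralityAssociationResults",
    "run_sensitivity_suite",
]

logger = logging.getLogger(__name__)

#: hospital size/resource blocks (available without the outcomes stage)
RESOURCE_BLOCKS = (
    "bed_category",
    "icu_category",
    "trauma_level",
    "fellowship",
    "teaching_status",
)

#: characteristic blocks of the primary multivariable model, in table order
DEFAULT_BLOCKS = (
    "bed_category",
    "icu_category",
    "trauma_level",
    "fellowship",
    "teaching_status",
    "volume_quartile",
    "mortality_quartile",
    "ftr_quartile",
)

#: reference-first level orders per characteristic
LEVEL_ORDERS: Mapping[str, tuple[str, ...]] = {
    "bed_category": ("0-100", "101-250", ">250"),
    "icu_category": ("0-10", "11-25", ">25"),
    "trauma_level": ("none", "3", "2", "1"),
    "fellowship": ("no", "yes"),
    "teaching_status": ("nonteaching", "small", "large"),
    "volume_quartile": ("Q1", "Q2", "Q3", "Q4"),
    "mortality_quartile": ("Q1", "Q2", "Q3", "Q4"),
    "ftr_quartile": ("Q1", "Q2", "Q3", "Q4"),
}


def _bed_category(beds: pd.Series) -> pd.Series:
    return pd.cut(
        beds, [0, 100, 250, np.inf], labels=["0-100", "101-250", ">250"]
    ).astype(str)


def _icu_category(beds: pd.Series) -> pd.Series:
    return pd.cut(beds, [-1, 10, 25, np.inf], labels=["0-10", "11-25", ">25"]).astype(str)


def build_analysis_frame(
    centrality: pd.DataFrame,
    hospitals: pd.DataFrame,
    outcomes: pd.DataFrame | None,
    network_label: str = "all",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join centrality records with hospital attributes and outcomes.

    Returns one row per hospital with a defined log centrality ratio and
    complete characteristics (listwise deletion), plus a tally of exclusions.
    With ``outcomes=None`` the quartile columns are omitted and the frame
    supports only the :data:`RESOURCE_BLOCKS` model.
    """
    cent = centrality[centrality["network_label"] == network_label]
    df = cent.merge(hospitals, on="hospital_id", how="left")
    if outcomes is not None:
        df = df.merge(outcomes, on="hospital_id", how="left")
    tally = {"hospitals_in_network": len(df)}

    cols = {
        "hospital_id": df["hospital_id"],
        "log_centrality_ratio": df["log_centrality_ratio"],
        "bed_category": _bed_category(df["total_beds"]),
        "icu_category": _icu_category(df["icu_beds"]),
        "trauma_level": df["trauma_level"].astype(str),
        "fellowship": np.where(df["fellowship"].astype("boolean").fillna(False), "yes", "no"),
        "teaching_status": df["teaching_status"].astype(str),
        "state": df["state"],
        "network_label": network_label,
    }
    if outcomes is not None:
        for col in ("volume_quartile", "mortality_quartile", "ftr_quartile"):
            # int() guards against the float upcast of masked integer columns
            cols[col] = df[col].map(lambda q: f"Q{int(q)}", na_action="ignore")
    out = pd.DataFrame(cols)
    defined = out["log_centrality_ratio"].notna()
    tally["undefined_log_ratio"] = int((~defined).sum())
    out = out[defined]
    complete = out.notna().all(axis=1)
    tally["missing_characteristics"] = int((~complete).sum())
    out = out[complete].reset_index(drop=True)
    tally["analyzed"] = len(out)
    for col, order in LEVEL_ORDERS.items():
        if col not in out.columns:
            continue
        observed = [lv for lv in order if lv in set(out[col])]
        out[col] = pd.Categorical(out[col], categories=observed, ordered=True)
    return out, tally


@dataclass
class AnovaResult:
    """One-way ANOVA of log centrality ratio across one characteristic."""

    characteristic: str
    f_statistic: float
    p_value: float
    group_summary: pd.DataFrame  # level, n, mean, sd
    pairwise: pd.DataFrame | None  # level_a, level_b, difference, ci_low, ci_high, p_adj
    posthoc_method: str
    dropped_levels: tuple[str, ...] = ()

    def difference(self, level_a: str, level_b: str) -> float:
        """Mean(level_a) - mean(level_b) from the pairwise table."""
        gs = self.group_summary.set_index("level")["mean"]
        return float(gs[level_a] - gs[level_b])

    def to_dict(self) -> dict:
        return {
            "characteristic": self.characteristic,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "posthoc_method": self.posthoc_method,
            "groups": self.group_summary.to_dict(orient="records"),
            "pairwise": None
            if self.pairwise is None
            else self.pairwise.to_dict(orient="records"),
            "dropped_levels": list(self.dropped_levels),
        }


def anova_with_pairwise(
    frame: pd.DataFrame,
    characteristic: str,
    outcome: str = "log_centrality_ratio",
    posthoc: str = "tukey",
) -> AnovaResult:
    """One-way ANOVA plus post hoc pairwise contrasts for one characteristic.

    ``posthoc`` is one of ``"tukey"`` (simultaneous HSD intervals, default),
    ``"bonferroni"``, ``"none"`` (unadjusted pairwise t), or ``"skip"`` (no
    pairwise table). Groups with fewer than 2 observations are dropped with a
    warning.
    """
    data = frame[[characteristic, outcome]].dropna()
    sizes = data.groupby(characteristic, observed=True).size()
    small = tuple(str(lv) for lv in sizes[sizes < 2].index)
    if small:
        logger.warning("%s: dropping groups with <2 observations: %s", characteristic, small)
        data = data[~data[characteristic].isin(small)]
    groups = [g[outcome].to_numpy() for _, g in data.groupby(characteristic, observed=True)]
    if len(groups) < 2:
        raise ValueError(f"{characteristic}: fewer than 2 usable groups")

    grand = np.concatenate(groups)
    if np.ptp(grand) == 0 or all(np.ptp(g) == 0 and g[0] == grand[0] for g in groups):
        f_stat, p_val = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p_val = scipy.stats.f_oneway(*groups)
        if np.isnan(f_stat):  # zero within-group variance with distinct means
            f_stat, p_val = np.inf, 0.0

    summary = (
        data.groupby(characteristic, observed=True)[outcome]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .rename(columns={characteristic: "level"})
    )
    summary["level"] = summary["level"].astype(str)

    pairwise: pd.DataFrame | None = None
    if posthoc != "skip":
        y = data[outcome].to_numpy()
        labels = data[characteristic].astype(str).to_numpy()
        if posthoc == "tukey":
            from itertools import combinations

            tk = pairwise_tukeyhsd(y, labels, alpha=0.05)
            pairs = list(combinations(tk.groupsunique, 2))
            pairwise = pd.DataFrame(
                {
                    "level_a": [a for a, _ in pairs],
                    "level_b": [b for _, b in pairs],
                    # statsmodels reports mean(group2) - mean(group1), i.e. b - a
                    "difference": tk.meandiffs.astype(float),
                    "ci_low": tk.confint[:, 0].astype(float),
                    "ci_high": tk.confint[:, 1].astype(float),
                    "p_adj": np.asarray(tk.pvalues, dtype=float),
                }
            )
        elif posthoc in ("none", "bonferroni"):
            levels = sorted(set(labels))
            pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
            m = len(pairs)
            recs = []
            for a, b in pairs:
                ya, yb = y[labels == a], y[labels == b]
                diff = float(yb.mean() - ya.mean())
                nA, nB = len(ya), len(yb)
                sp2 = ((nA - 1) * ya.var(ddof=1) + (nB - 1) * yb.var(ddof=1)) / (nA + nB - 2)
                se = np.sqrt(sp2 * (1 / nA + 1 / nB))
                dfree = nA + nB - 2
                if se == 0:
                    p = 1.0 if diff == 0 else 0.0
                    lo = hi = diff
                else:
                    t = diff / se
                    p = 2 * scipy.stats.t.sf(abs(t), dfree)
                    crit = scipy.stats.t.ppf(0.975, dfree)
                    lo, hi = diff - crit * se, diff + crit * se
                p_adj = min(1.0, p * m) if posthoc == "bonferroni" else p
                recs.append((a, b, diff, lo, hi, p_adj))
            pairwise = pd.DataFrame(
                recs,
                columns=["level_a", "level_b", "difference", "ci_low", "ci_high", "p_adj"],
            )
        else:
            raise ValueError(f"unknown posthoc method {posthoc!r}")

    return AnovaResult(
        characteristic=characteristic,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        group_summary=summary,
        pairwise=pairwise,
        posthoc_method=posthoc,
        dropped_levels=small,
    )


class CentralityAssociationModel:
    """Multivariable OLS of log centrality ratio on hospital characteristics.

    Parameters
    ----------
    frame : analysis frame from :func:`build_analysis_frame`.
    blocks : characteristic blocks entering the design (default all eight).
    cluster_col : column defining error clusters (default ``"state"``).
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        blocks: Sequence[str] = DEFAULT_BLOCKS,
        cluster_col: str = "state",
        outcome: str = "log_centrality_ratio",
    ) -> None:
        self.frame = frame.dropna(subset=[outcome, cluster_col, *blocks]).reset_index(drop=True)
        for b in blocks:
            if not isinstance(self.frame[b].dtype, pd.CategoricalDtype):
                values = self.frame[b].astype(str)
                order = [
                    lv for lv in LEVEL_ORDERS.get(b, tuple(sorted(values.unique())))
                    if lv in set(values)
                ]
                self.frame[b] = pd.Categorical(values, categories=order, ordered=True)
            else:
                observed = [
                    lv for lv in self.frame[b].cat.categories
                    if (self.frame[b] == lv).any()
                ]
                self.frame[b] = self.frame[b].cat.set_categories(observed, ordered=True)
        self.blocks = tuple(blocks)
        self.cluster_col = cluster_col
        self.outcome = outcome
        if self.frame[cluster_col].nunique() < 2:
            raise ValueError("clustered inference requires at least 2 clusters")
        terms = []
        self._block_of_term: dict[str, str] = {}
        for b in self.blocks:
            term = f"C({b})"
            terms.append(term)
            self._block_of_term[term] = b
        self.formula = f"{outcome} ~ " + " + ".join(terms)

    def fit(self, cov_type: str = "cluster") -> "CentralityAssociationResults":
        model = smf.ols(self.formula, data=self.frame)
        # reject rank deficiency before fitting so the error names the culprit
        rank = np.linalg.matrix_rank(model.exog)
        if rank < model.exog.shape[1]:
            raise ValueError(
                "design matrix is rank deficient; collinear levels among "
                f"{self.blocks} (rank {rank} < {model.exog.shape[1]} columns)"
            )
        groups = self.frame[self.cluster_col]
        if cov_type == "cluster":
            res = model.fit(
                cov_type="cluster",
                cov_kwds={"groups": groups, "use_correction": True, "df_correction": True},
                use_t=True,
            )
        else:
            res = model.fit(cov_type=cov_type, use_t=True)
        return CentralityAssociationResults(self, res, n_clusters=int(groups.nunique()))


@dataclass
class CentralityAssociationResults:
    """Fitted association model with cluster-robust uncertainty."""

    model: CentralityAssociationModel
    _res: object  # statsmodels RegressionResults
    n_clusters: int

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        ci.columns = ["ci_low", "ci_high"]
        return ci

    def cov_params(self) -> pd.DataFrame:
        return self._res.cov_params()

    def _terms_of_block(self, block: str) -> list[str]:
        prefix = f"C({block})"
        return [p for p in self._res.params.index if p.startswith(prefix)]

    def coefficient_table(self) -> pd.DataFrame:
        """Long table of per-level estimates, reference rows pinned at 0."""
        ci = self.conf_int()
        rows = []
        for block in self.model.blocks:
            levels = list(self.model.frame[block].cat.categories)
            rows.append(
                {"block": block, "level": str(levels[0]), "beta": 0.0,
                 "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                 "reference": True}
            )
            for term in self._terms_of_block(block):
                level = term.split("[T.", 1)[1].rstrip("]")
                rows.append(
                    {"block": block, "level": level,
                     "beta": float(self._res.params[term]),
                     "ci_low": float(ci.loc[term, "ci_low"]),
                     "ci_high": float(ci.loc[term, "ci_high"]),
                     "p_value": float(self._res.pvalues[term]),
                     "reference": False}
                )
        return pd.DataFrame(rows)

    def partial_f_table(self) -> pd.DataFrame:
        """Wald partial-F test per characteristic block (clustered covariance)."""
        rows = []
        for block in self.model.blocks:
            terms = self._terms_of_block(block)
            if not terms:
                continue
            hyp = ", ".join(f"{t} = 0" for t in terms)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wt = self._res.wald_test(hyp, use_f=True, scalar=True)
            rows.append(
                {"block": block, "f_statistic": float(wt.statistic),
                 "df_num": int(wt.df_num), "df_denom": float(wt.df_denom),
                 "p_value": float(wt.pvalue)}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Readable coefficient table in the layout of hospital-profile reports."""
        coef = self.coefficient_table()
        pf = self.partial_f_table().set_index("block")["p_value"]
        lines = [
            f"Log centrality ratio ~ hospital characteristics "
            f"(n={self.nobs}, clusters={self.n_clusters}, "
            f"cluster-robust 95% CI, t df={self.n_clusters - 1})",
            f"{'characteristic':<22}{'level':<14}{'beta (95% CI)':<28}{'partial-F p':>12}",
        ]
        for block in self.model.blocks:
            sub = coef[coef["block"] == block]
            block_p = f"{pf.get(block, np.nan):.3g}"
            for k, (_, r) in enumerate(sub.iterrows()):
                beta = (
                    "0 [Reference]"
                    if r["reference"]
                    else f"{r['beta']:.2f} ({r['ci_low']:.2f} to {r['ci_high']:.2f})"
                )
                lines.append(
                    f"{block if k == 0 else '':<22}{r['level']:<14}{beta:<28}"
                    f"{block_p if k == 0 else '':>12}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_obs": self.nobs,
            "n_clusters": self.n_clusters,
            "coefficients": self.coefficient_table().to_dict(orient="records"),
            "partial_f": self.partial_f_table().to_dict(orient="records"),
        }


def run_sensitivity_suite(
    frames: Mapping[str, pd.DataFrame],
    blocks: Sequence[str] = DEFAULT_BLOCKS,
    cluster_col: str = "state",
) -> dict[str, CentralityAssociationResults | dict]:
    """Fit the identical multivariable model on each subnetwork frame.

    Degenerate frames (empty, single cluster, rank-deficient) produce a
    structured skip record instead of raising.
    """
    out: dict[str, CentralityAssociationResults | dict] = {}
    for label, frame in frames.items():
        if frame is None or len(frame) == 0:
            out[label] = {"skipped": True, "reason": "empty analysis frame"}
            continue
        try:
            out[label] = CentralityAssociationModel(
                frame, blocks=blocks, cluster_col=cluster_col
            ).fit()
        except (ValueError, np.linalg.LinAlgError) as exc:
            out[label] = {"skipped": True, "reason": str(exc)}
    return out
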