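"""Reproducible pipeline: simulate -> link -> network -> outcomes -> analyze.

Each stage reads and writes plain-text artifacts (CSV/TSV/JSON-lines) and the
run emits a JSON manifest carrying content hashes of every output, per-stage
row counts in/out, and exclusion tallies. Identical config + seed reproduce
byte-identical outputs, so manifest hashes certify a deterministic rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import codes as codes_mod
from . import inference, linkage, network, outcomes
from .simulate import SimulationConfig, generate_encounters, generate_hospitals

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "link", "network", "outcomes", "analyze")


class PipelineConfig(BaseModel):
    """Configuration of a full pipeline run."""

    model_config = {"frozen": True}

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = STAGES
    min_age: int = 18
    convention: str = "weighted"  # or "binary"
    posthoc: str = "tukey"
    networks: tuple[str, ...] = network.NETWORK_LABELS
    cluster_on: str = "state"
    codes_path: str | None = None  # None -> packaged synthetic fixture
    comorbidity_path: str | None = None

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = self.simulation.model_copy(update={"seed": seed})
        return self.model_copy(update={"simulation": sim})


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        obj = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d", **kw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages in order; return the run manifest.

    A stage failure is recorded in the manifest and downstream stages are
    skipped (the manifest, not an exception, reports the failure point).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    codeset = (
        codes_mod.load_codeset(config.codes_path)
        if config.codes_path
        else codes_mod.default_codeset()
    )
    comorbidity = (
        codes_mod.load_comorbidity_map(config.comorbidity_path)
        if config.comorbidity_path
        else codes_mod.default_comorbidity_map()
    )

    manifest: dict = {
        "seed": config.simulation.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": [],
    }
    state: dict = {}
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if failed:
            manifest["stages"].append({"name": stage, "status": "skipped"})
            continue
        t0 = time.perf_counter()
        rec: dict = {"name": stage, "status": "ok", "outputs": {}}
        try:
            _STAGE_FNS[stage](config, out, codeset, comorbidity, state, rec)
        except Exception as exc:  # pragma: no cover - exercised via toggles
            logger.exception("stage %s failed", stage)
            rec["status"] = "failed"
            rec["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
        rec["seconds"] = round(time.perf_counter() - t0, 3)
        for name in rec["outputs"]:
            rec["outputs"][name] = _sha256(out / name)
        manifest["stages"].append(rec)

    manifest["completed_stages"] = sum(
        1 for s in manifest["stages"] if s["status"] == "ok"
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config, out, codeset, comorbidity, state, rec):
    hospitals = generate_hospitals(config.simulation)
    encounters, truth = generate_encounters(
        hospitals, config.simulation, codeset, comorbidity
    )
    _write_csv(hospitals, out / "hospitals.csv")
    _write_csv(encounters, out / "encounters.csv")
    truth.to_json(out / "ground_truth.json")
    state.update(hospitals=hospitals, encounters=encounters, truth=truth)
    rec["rows_out"] = {"hospitals": len(hospitals), "encounters": len(encounters)}
    rec["outputs"] = {"hospitals.csv": "", "encounters.csv": "", "ground_truth.json": ""}


def _stage_link(config, out, codeset, comorbidity, state, rec):
    if "encounters" not in state:
        state["encounters"] = linkage.load_encounters(out / "encounters.csv")
    anomalies: list[str] = []
    episodes = linkage.build_episodes(state["encounters"], codeset, anomalies)
    cohort = linkage.filter_transfer_cohort(episodes, config.min_age)
    transfers = linkage.transfers_frame(cohort)
    cohort_hospitals = sorted(
        {e.hospital_id for ep in cohort for e in ep.encounters}
    )
    ep_frame = outcomes.episode_table(episodes, codeset, comorbidity, config.min_age)

    _write_csv(transfers, out / "transfers.csv")
    _write_csv(ep_frame, out / "episode_table.csv")
    (out / "cohort_hospitals.csv").write_text(
        "hospital_id\n" + "".join(h + "\n" for h in cohort_hospitals)
    )
    with open(out / "episodes.jsonl", "w") as fh:
        for ep in episodes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": ep.patient_id,
                        "egs": ep.egs,
                        "egs_category": ep.egs_category,
                        "n_encounters": len(ep.encounters),
                        "hospitals": [e.hospital_id for e in ep.encounters],
                        "transfers": [
                            [t.origin_hospital, t.destination_hospital,
                             t.transfer_type, t.any_operation]
                            for t in ep.transfer_events
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    state.update(episodes=episodes, cohort=cohort, transfers=transfers,
                 cohort_hospitals=cohort_hospitals, episode_table=ep_frame)
    rec["rows_in"] = {"encounters": len(state["encounters"])}
    rec["rows_out"] = {
        "episodes": len(episodes),
        "transfer_cohort_episodes": len(cohort),
        "transfers": len(transfers),
        "egs_inpatient_episodes": len(ep_frame),
    }
    rec["exclusions"] = {"overlap_anomalies": len(anomalies)}
    rec["outputs"] = {
        "transfers.csv": "", "episode_table.csv": "",
        "cohort_hospitals.csv": "", "episodes.jsonl": "",
    }


def _stage_network(config, out, codeset, comorbidity, state, rec):
    if "transfers" not in state:
        state["transfers"] = pd.read_csv(out / "transfers.csv")
        state["cohort_hospitals"] = (
            pd.read_csv(out / "cohort_hospitals.csv")["hospital_id"].astype(str).tolist()
        )
    cent, exclusions = network.centrality_table(
        state["transfers"], state["cohort_hospitals"], config.convention, config.networks
    )
    _write_csv(cent, out / "centrality.csv")
    rec["outputs"] = {"centrality.csv": ""}
    for label in config.networks:
        g = network.build_network(state["transfers"], label, state["cohort_hospitals"])
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in sorted(g.edges(data=True))],
            columns=["origin", "destination", "weight"],
        )
        fname = f"edges_{label}.tsv"
        edges.to_csv(out / fname, sep="\t", index=False)
        rec["outputs"][fname] = ""
    state["centrality"] = cent
    rec["rows_in"] = {"transfers": len(state["transfers"])}
    rec["rows_out"] = {"centrality_records": len(cent)}
    rec["exclusions"] = {
        label: {"undefined_ratio": e.n_undefined, "zero_ratio": e.n_zero}
        for label, e in exclusions.items()
    }
    rec["convention"] = config.convention


def _stage_outcomes(config, out, codeset, comorbidity, state, rec):
    if "episode_table" not in state:
        state["episode_table"] = pd.read_csv(out / "episode_table.csv")
    ep = state["episode_table"]
    mort = outcomes.EpisodeRiskModel(ep, outcome="death").fit()
    try:
        ftr = outcomes.EpisodeRiskModel(ep, outcome="ftr").fit()
    except outcomes.RiskModelError as exc:
        logger.warning("failure-to-rescue model not fitted: %s", exc)
        ftr = None
    table = outcomes.hospital_outcomes_table(ep, mort, ftr)
    _write_csv(table, out / "hospital_outcomes.csv")
    coeffs = {
        "death": mort.coefficients(),
        "death_overall_rate": mort.overall_rate,
        "ftr": None if ftr is None else ftr.coefficients(),
        "ftr_overall_rate": None if ftr is None else ftr.overall_rate,
    }
    (out / "risk_model_coefficients.json").write_text(
        json.dumps(coeffs, indent=1, sort_keys=True)
    )
    state.update(hospital_outcomes=table, mortality_model=mort, ftr_model=ftr)
    rec["rows_in"] = {"egs_inpatient_episodes": len(ep)}
    rec["rows_out"] = {"hospitals": len(table)}
    rec["outputs"] = {"hospital_outcomes.csv": "", "risk_model_coefficients.json": ""}


def _stage_analyze(config, out, codeset, comorbidity, state, rec):
    if "centrality" not in state:
        state["centrality"] = pd.read_csv(out / "centrality.csv")
    if "hospital_outcomes" not in state:
        state["hospital_outcomes"] = pd.read_csv(out / "hospital_outcomes.csv")
    if "hospitals" not in state:
        state["hospitals"] = pd.read_csv(out / "hospitals.csv")

    frames: dict[str, pd.DataFrame] = {}
    tallies: dict[str, dict] = {}
    for label in config.networks:
        frames[label], tallies[label] = inference.build_analysis_frame(
            state["centrality"], state["hospitals"], state["hospital_outcomes"], label
        )
    main = frames.get("all", next(iter(frames.values())))

    anova = {
        block: inference.anova_with_pairwise(main, block, posthoc=config.posthoc).to_dict()
        for block in inference.DEFAULT_BLOCKS
    }
    primary = inference.CentralityAssociationModel(
        main, cluster_col=config.cluster_on
    ).fit()
    sens_labels = [lb for lb in config.networks if lb != "all"]
    sensitivity = inference.run_sensitivity_suite(
        {lb: frames[lb] for lb in sens_labels}, cluster_col=config.cluster_on
    )

    results = {
        "anova": anova,
        "regression": primary.to_dict(),
        "sensitivity": {
            lb: (r.to_dict() if hasattr(r, "to_dict") else r)
            for lb, r in sensitivity.items()
        },
        "exclusions": tallies,
    }
    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    coef = primary.coefficient_table()
    coef.insert(0, "network_label", "all")
    extra = [
        r.coefficient_table().assign(network_label=lb)
        for lb, r in sensitivity.items()
        if hasattr(r, "coefficient_table")
    ]
    flat = pd.concat([coef, *extra], ignore_index=True)
    _write_csv(flat, out / "coefficients.csv")
    state.update(analysis_results=results, primary_results=primary)
    rec["rows_in"] = {"analysis_hospitals": len(main)}
    rec["rows_out"] = {"coefficient_rows": len(flat)}
    rec["exclusions"] = tallies
    rec["outputs"] = {"results.json": "", "coefficients.csv": ""}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "link": _stage_link,
    "network": _stage_network,
    "outcomes": _stage_outcomes,
    "analyze": _stage_analyze,
}
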