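"""Weighted directed transfer networks and degree-centrality ratios.

Hospitals are nodes; an edge A -> B carries the number of transfers from A to
B. Five networks are built from one transfer list: all transfers, ED-to-
inpatient only, inpatient-to-inpatient only, transfers involving at least one
operation or procedure, and transfers involving none.

Two degree conventions are implemented:

``weighted`` (default)
    in-degree = (sum of incoming edge weights) / ((n - 1) * W_max), where n is
    the node count and W_max the largest edge weight in the network; the
    analogous expression for out-degree. Values lie in [0, 1] and are scaled
    by 10 000. Under this convention the centrality *ratio* reduces to
    (incoming transfer count) / (outgoing transfer count) because the
    normalisation cancels.

``binary``
    in-degree = (number of distinct in-neighbours) / (n - 1), likewise scaled.

The ratio is undefined for hospitals with no outgoing transfers and its log
is undefined when the ratio is zero; both are excluded (and tallied) rather
than offset, unless an explicit ``epsilon`` pseudo-count is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_LABELS",
    "SCALE",
    "build_network",
    "build_all_networks",
    "degree_centralities",
    "log_transform_ratios",
    "centrality_table",
]

#: canonical network labels, in presentation order
NETWORK_LABELS = ("all", "ed_to_ip", "ip_to_ip", "with_operation", "without_operation")

SCALE = 10_000.0


def _select(transfers: pd.DataFrame, label: str) -> pd.DataFrame:
    if label == "all":
        return transfers
    if label == "ed_to_ip":
        return transfers[transfers["transfer_type"] == "ED->IP"]
    if label == "ip_to_ip":
        return transfers[transfers["transfer_type"] == "IP->IP"]
    if label == "with_operation":
        return transfers[transfers["any_operation"].astype(bool)]
    if label == "without_operation":
        return transfers[~transfers["any_operation"].astype(bool)]
    raise ValueError(f"unknown network label {label!r}; expected one of {NETWORK_LABELS}")


def build_network(
    transfers: pd.DataFrame,
    label: str = "all",
    nodes: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Aggregate a transfer list into one weighted directed network.

    Parameters
    ----------
    transfers : DataFrame with columns
        ``origin_hospital, destination_hospital, transfer_type, any_operation``.
    label : which of the five networks to build (see :data:`NETWORK_LABELS`).
    nodes : optional full node set (hospitals appearing in any retained
        encounter). Isolates are kept — they still enter the normalisation.
    """
    sub = _select(transfers, label)
    g = nx.DiGraph(network_label=label)
    if nodes is not None:
        g.add_nodes_from(sorted(map(str, nodes)))
    if len(sub):
        counts = (
            sub.groupby(["origin_hospital", "destination_hospital"])
            .size()
            .reset_index(name="weight")
        )
        for o, d, w in counts.itertuples(index=False):
            if o == d:
                raise ValueError(f"self-loop transfer {o} -> {d}")
            g.add_edge(str(o), str(d), weight=int(w))
    return g


def build_all_networks(
    transfers: pd.DataFrame, nodes: Iterable[str] | None = None
) -> dict[str, nx.DiGraph]:
    return {label: build_network(transfers, label, nodes) for label in NETWORK_LABELS}


def degree_centralities(
    network: nx.DiGraph, convention: str = "weighted"
) -> pd.DataFrame:
    """Per-hospital scaled in/out-degree centrality and centrality ratio.

    Returns a DataFrame indexed 0..n-1 with columns ``hospital_id,
    in_degree_scaled, out_degree_scaled, centrality_ratio, network_label``.
    The ratio is NaN where out-degree is zero.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError(f"degenerate network: {n} node(s); need at least 2")
    if convention not in ("weighted", "binary"):
        raise ValueError(f"unknown degree convention {convention!r}")

    nodes = sorted(network.nodes)
    if convention == "weighted":
        w_max = max((d["weight"] for _, _, d in network.edges(data=True)), default=1)
        denom = (n - 1) * w_max
        in_raw = np.array([network.in_degree(v, weight="weight") for v in nodes], float)
        out_raw = np.array([network.out_degree(v, weight="weight") for v in nodes], float)
    else:
        denom = n - 1
        in_raw = np.array([network.in_degree(v) for v in nodes], float)
        out_raw = np.array([network.out_degree(v) for v in nodes], float)

    in_scaled = in_raw / denom * SCALE
    out_scaled = out_raw / denom * SCALE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(out_scaled > 0, in_scaled / out_scaled, np.nan)
    return pd.DataFrame(
        {
            "hospital_id": nodes,
            "in_degree_scaled": in_scaled,
            "out_degree_scaled": out_scaled,
            "centrality_ratio": ratio,
            "network_label": network.graph.get("network_label", "all"),
        }
    )


@dataclass(frozen=True)
class RatioExclusions:
    """Tally of hospitals dropped from log-ratio analyses."""

    n_hospitals: int
    n_undefined: int  # out-degree zero
    n_zero: int  # in-degree zero (ratio exactly 0)

    @property
    def n_analyzed(self) -> int:
        return self.n_hospitals - self.n_undefined - self.n_zero


def log_transform_ratios(
    records: pd.DataFrame, epsilon: float = 0.0
) -> tuple[pd.DataFrame, RatioExclusions]:
    """Attach the natural-log centrality ratio, excluding undefined/zero ratios.

    With ``epsilon > 0`` a pseudo-count is added to both raw degrees before
    taking the ratio (off by default; exclusion matches the reduced per-network
    hospital counts reported in claims analyses).
    """
    out = records.copy()
    ratio = out["centrality_ratio"].to_numpy(dtype=float)
    if epsilon > 0:
        ratio = (out["in_degree_scaled"].to_numpy() + epsilon) / (
            out["out_degree_scaled"].to_numpy() + epsilon
        )
    undefined = np.isnan(ratio)
    zero = ~undefined & (ratio <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.where(undefined | zero, np.nan, np.log(np.where(ratio > 0, ratio, 1.0)))
    out["log_centrality_ratio"] = logr
    excl = RatioExclusions(
        n_hospitals=len(out), n_undefined=int(undefined.sum()), n_zero=int(zero.sum())
    )
    return out, excl


def centrality_table(
    transfers: pd.DataFrame,
    nodes: Iterable[str] | None = None,
    convention: str = "weighted",
    labels: Sequence[str] = NETWORK_LABELS,
) -> tuple[pd.DataFrame, dict[str, RatioExclusions]]:
    """Centrality records (with log ratios) for the selected networks, stacked."""
    frames = []
    exclusions: dict[str, RatioExclusions] = {}
    for label in labels:
        g = build_network(transfers, label, nodes)
        rec = degree_centralities(g, convention)
        rec, excl = log_transform_ratios(rec)
        frames.append(rec)
        exclusions[label] = excl
    return pd.concat(frames, ignore_index=True), exclusions
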