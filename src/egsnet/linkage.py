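"""Episode-of-care construction and interhospital transfer identification.

An episode of care is a maximal chain of temporally adjacent encounters for
one patient. Two encounters are *temporally adjacent* when the discharge date
of the first is on the same day or the previous day of the admission date of
the second. A chain link is followed when the encounters are at different
hospitals (a transfer candidate) or when an ED-only visit is followed by an
inpatient admission at the same hospital (an ED visit that resulted in
admission). Same-hospital inpatient-to-inpatient adjacency is treated as a
readmission and starts a new episode.

A :class:`TransferEvent` is emitted for every cross-hospital adjacent pair
whose downstream portion resolves to an inpatient encounter at the destination
hospital; ED-to-ED links that end in an inpatient admission at the second
hospital are therefore typed ``ED->IP``. An episode counts as an EGS episode
when at least one *inpatient* encounter carries an EGS diagnosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codes import CodeSet, normalize_code

__all__ = [
    "Encounter",
    "TransferEvent",
    "Episode",
    "LinkageError",
    "is_temporally_adjacent",
    "flag_operation",
    "build_episodes",
    "filter_transfer_cohort",
    "transfers_frame",
    "load_encounters",
]

logger = logging.getLogger(__name__)

ED = "ED"
IP = "IP"
ED_IP = "ED->IP"
IP_IP = "IP->IP"

ENCOUNTER_COLUMNS = (
    "patient_id", "hospital_id", "state", "setting", "admit_date",
    "discharge_date", "age", "sex", "dx_codes", "proc_codes", "died",
)


class LinkageError(ValueError):
    """Raised for unusable encounter input (bad dates, mixed patients)."""


@dataclass(frozen=True)
class Encounter:
    """One hospital visit (ED-only or inpatient)."""

    patient_id: str
    hospital_id: str
    state: str
    setting: str  # ED or IP
    admit_day: int  # days since an arbitrary epoch
    discharge_day: int
    age: int
    sex: str
    dx_codes: frozenset[str]
    proc_codes: frozenset[str]
    died: bool

    def __post_init__(self) -> None:
        if self.discharge_day < self.admit_day:
            raise LinkageError(
                f"encounter for {self.patient_id}: discharge before admission"
            )


@dataclass(frozen=True)
class TransferEvent:
    """An ordered origin -> destination hospital transfer."""

    patient_id: str
    origin_hospital: str
    destination_hospital: str
    transfer_type: str  # ED->IP or IP->IP
    any_operation: bool

    def __post_init__(self) -> None:
        if self.origin_hospital == self.destination_hospital:
            raise LinkageError("transfer with origin == destination")


@dataclass
class Episode:
    """A patient's chain of temporally adjacent encounters."""

    patient_id: str
    encounters: list[Encounter]
    transfer_events: list[TransferEvent] = field(default_factory=list)
    egs: bool = False
    egs_category: str | None = None

    @property
    def transferred(self) -> bool:
        return bool(self.transfer_events)

    @property
    def inpatient(self) -> bool:
        return any(e.setting == IP for e in self.encounters)

    @property
    def age_at_first(self) -> int:
        return self.encounters[0].age

    @property
    def treating_hospital(self) -> str:
        """Hospital of the last inpatient encounter (outcome attribution)."""
        for e in reversed(self.encounters):
            if e.setting == IP:
                return e.hospital_id
        return self.encounters[-1].hospital_id

    @property
    def died(self) -> bool:
        return any(e.died for e in self.encounters)

    def all_dx(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.encounters:
            out.update(e.dx_codes)
        return frozenset(out)


def is_temporally_adjacent(first: Encounter, second: Encounter) -> bool:
    """Cross-hospital temporal adjacency between two encounters of one patient.

    True iff the second admission is on the same day or the day after the
    first discharge, and the hospitals differ.
    """
    if first.patient_id != second.patient_id:
        raise LinkageError("is_temporally_adjacent: encounters belong to different patients")
    gap = second.admit_day - first.discharge_day
    return gap in (0, 1) and first.hospital_id != second.hospital_id


def flag_operation(encounter: Encounter, codes: CodeSet) -> bool:
    """True iff the encounter carries any operation/procedure code."""
    return bool(encounter.proc_codes & codes.operation_proc)


def _split_codes(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return frozenset()
    if isinstance(raw, str):
        parts = raw.split(";")
    else:
        parts = raw
    return frozenset(normalize_code(p) for p in parts if str(p).strip())


def load_encounters(path: str | Path) -> pd.DataFrame:
    """Read an encounters CSV, validating schema and dates.

    Unparseable dates raise :class:`LinkageError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "hospital_id": str})
    missing = set(ENCOUNTER_COLUMNS) - set(df.columns)
    if missing:
        raise LinkageError(f"encounters file missing columns: {sorted(missing)}")
    for col in ("admit_date", "discharge_date"):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise LinkageError(f"unparseable {col} at row index {int(bad.idxmax())}")
        if parsed.isna().any():
            raise LinkageError(f"missing {col} at row index {int(parsed.isna().idxmax())}")
        df[col] = parsed
    return df


def _to_encounters(df: pd.DataFrame) -> list[Encounter]:
    admit = pd.to_datetime(df["admit_date"])
    disc = pd.to_datetime(df["discharge_date"])
    admit_day = (admit.astype("int64") // 86_400_000_000_000).to_numpy()
    disc_day = (disc.astype("int64") // 86_400_000_000_000).to_numpy()
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        setting = str(row.setting).upper()
        if setting not in (ED, IP):
            # tolerate the long-form labels used in some claims extracts
            setting = ED if "ED" in setting else IP
        out.append(
            Encounter(
                patient_id=str(row.patient_id),
                hospital_id=str(row.hospital_id),
                state=str(row.state),
                setting=setting,
                admit_day=int(admit_day[i]),
                discharge_day=int(disc_day[i]),
                age=int(row.age),
                sex=str(row.sex),
                dx_codes=_split_codes(row.dx_codes),
                proc_codes=_split_codes(row.proc_codes),
                died=bool(int(row.died)),
            )
        )
    return out


def _chainable(prev: Encounter, cur: Encounter) -> bool:
    gap = cur.admit_day - prev.discharge_day
    if gap not in (0, 1):
        return False
    if prev.hospital_id != cur.hospital_id:
        return True
    # same hospital: only an ED visit resulting in admission continues the chain
    return prev.setting == ED and cur.setting == IP


def _resolves_inpatient(chain: Sequence[Encounter], j: int) -> bool:
    """Does the encounter at position j (or its same-hospital continuation) reach IP?"""
    if chain[j].setting == IP:
        return True
    k = j
    while k + 1 < len(chain) and chain[k + 1].hospital_id == chain[j].hospital_id:
        if chain[k + 1].setting == IP:
            return True
        k += 1
    return False


def _destination_operation(chain: Sequence[Encounter], j: int, codes: CodeSet) -> bool:
    """Operation at the destination encounter or its same-hospital continuation."""
    if flag_operation(chain[j], codes):
        return True
    k = j
    while k + 1 < len(chain) and chain[k + 1].hospital_id == chain[j].hospital_id:
        if flag_operation(chain[k + 1], codes):
            return True
        k += 1
    return False


def build_episodes(
    encounters: pd.DataFrame | Iterable[Encounter],
    codes: CodeSet,
    anomalies: list | None = None,
) -> list[Episode]:
    """Group encounters into episodes of care and emit transfer events.

    Per patient, encounters are sorted by admission date (ties broken by
    discharge date, then hospital id) and greedily chained under the temporal
    adjacency rule. Temporally overlapping encounters at different hospitals
    are not linked; they are logged as data anomalies (appended to
    ``anomalies`` when a list is supplied) and start a new episode.
    """
    if isinstance(encounters, pd.DataFrame):
        enc_list = _to_encounters(encounters)
    else:
        enc_list = list(encounters)

    enc_list.sort(
        key=lambda e: (e.patient_id, e.admit_day, e.discharge_day, e.hospital_id)
    )
    episodes: list[Episode] = []

    def _close(chain: list[Encounter]) -> None:
        ep = Episode(patient_id=chain[0].patient_id, encounters=chain)
        egs_dx = codes.egs_dx
        ip_dx: set[str] = set()
        for e in chain:
            if e.setting == IP:
                ip_dx.update(e.dx_codes)
        matched = ip_dx & egs_dx
        ep.egs = bool(matched)
        if matched:
            ep.egs_category = codes.egs_category_of(matched)
        for i in range(len(chain) - 1):
            a, b = chain[i], chain[i + 1]
            if a.hospital_id == b.hospital_id:
                continue
            if not _resolves_inpatient(chain, i + 1):
                continue
            ep.transfer_events.append(
                TransferEvent(
                    patient_id=ep.patient_id,
                    origin_hospital=a.hospital_id,
                    destination_hospital=b.hospital_id,
                    transfer_type=ED_IP if a.setting == ED else IP_IP,
                    any_operation=flag_operation(a, codes)
                    or _destination_operation(chain, i + 1, codes),
                )
            )
        episodes.append(ep)

    chain: list[Encounter] = []
    for e in enc_list:
        if not chain:
            chain = [e]
            continue
        prev = chain[-1]
        if e.patient_id != prev.patient_id:
            _close(chain)
            chain = [e]
            continue
        if e.admit_day < prev.discharge_day and e.hospital_id != prev.hospital_id:
            msg = (
                f"overlapping encounters for patient {e.patient_id}: "
                f"{prev.hospital_id} and {e.hospital_id}"
            )
            logger.warning("%s — not linked", msg)
            if anomalies is not None:
                anomalies.append(msg)
            _close(chain)
            chain = [e]
            continue
        if _chainable(prev, e):
            chain.append(e)
        else:
            _close(chain)
            chain = [e]
    if chain:
        _close(chain)
    return episodes


def filter_transfer_cohort(episodes: Iterable[Episode], min_age: int = 18) -> list[Episode]:
    """Adult EGS episodes that involved at least one interhospital transfer."""
    return [
        ep
        for ep in episodes
        if ep.egs and ep.transfer_events and ep.age_at_first >= min_age
    ]


def transfers_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Flatten episodes' transfer events into a tidy DataFrame."""
    rows = [
        (t.patient_id, t.origin_hospital, t.destination_hospital,
         t.transfer_type, t.any_operation)
        for ep in episodes
        for t in ep.transfer_events
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "origin_hospital", "destination_hospital",
                 "transfer_type", "any_operation"],
    )
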