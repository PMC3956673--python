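"""Event logs: the lingua franca between simulator, fixtures and analysis.

One :class:`EventLog` holds every activation of one run as parallel numpy
arrays in activation order.  The on-disk format is plain CSV with header
``run,period,activation_index,event_type,actor,partner,aggressor,victim,
winner,x,y`` (UTF-8, '.' decimal, empty cells for missing fields).
Also houses the adapter that maps timestamped observational records of real
groups onto the same PC-MC structures used for model logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EVENT_MOVE = 0
EVENT_SEARCH = 1
EVENT_FIGHT = 2
EVENT_GROOM = 3
EVENT_NAMES = np.array(["move", "search", "fight", "groom"])
_EVENT_CODES = {name: code for code, name in enumerate(EVENT_NAMES)}

NONE_ID = -1  # sentinel for "no individual" in id columns


class LogFormatError(ValueError):
    """Malformed event-log file (message carries the offending line number)."""


@dataclass
class EventLog:
    """A single run's behavioural record, strictly ordered by activation.

    ``clock`` (the global activation counter) is implicit: row ``t`` happened
    at clock ``t``; equivalently ``clock = (period - 1) * activations_per_period
    + activation_index`` with 1-based periods and 0-based within-period index.
    """

    run: int
    activations_per_period: int
    burn_in_periods: int
    period: np.ndarray
    index: np.ndarray
    event: np.ndarray
    actor: np.ndarray
    partner: np.ndarray
    aggressor: np.ndarray
    victim: np.ndarray
    winner: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.event)

    @property
    def clock(self) -> np.ndarray:
        return (self.period.astype(np.int64) - 1) * self.activations_per_period + self.index

    @property
    def collected(self) -> np.ndarray:
        """Mask of events inside the collection window (periods > burn-in)."""
        return self.period > self.burn_in_periods

    def n_events(self, code: int, collected_only: bool = True) -> int:
        m = self.event == code
        if collected_only:
            m &= self.collected
        return int(m.sum())

    # ---------------------------------------------------------------- frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.full(len(self), self.run, dtype=np.int32),
                "period": self.period,
                "activation_index": self.index,
                "event_type": EVENT_NAMES[self.event],
                "actor": self.actor,
                "partner": self.partner,
                "aggressor": self.aggressor,
                "victim": self.victim,
                "winner": self.winner,
                "x": self.x,
                "y": self.y,
            }
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        for col in ("partner", "aggressor", "victim", "winner"):
            df[col] = df[col].astype(object)
            df.loc[df[col] == NONE_ID, col] = ""
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, activations_per_period: int | None = None,
                 burn_in_periods: int = 0) -> "EventLog":
        df = pd.read_csv(path, keep_default_na=True)
        expected = ["run", "period", "activation_index", "event_type", "actor",
                    "partner", "aggressor", "victim", "winner", "x", "y"]
        if list(df.columns) != expected:
            raise LogFormatError(f"bad header: expected {expected}, got {list(df.columns)}")

        def ids(col):
            return df[col].fillna(NONE_ID).astype(np.int32).to_numpy()

        bad_type = ~df["event_type"].isin(EVENT_NAMES)
        if bad_type.any():
            line = int(np.flatnonzero(bad_type.to_numpy())[0]) + 2  # header is line 1
            raise LogFormatError(f"line {line}: unknown event_type {df['event_type'].iloc[line - 2]!r}")
        event = np.array([_EVENT_CODES[t] for t in df["event_type"]], dtype=np.int8)
        actor = ids("actor")
        partner, aggressor, victim, winner = (ids(c) for c in ("partner", "aggressor", "victim", "winner"))

        fights = event == EVENT_FIGHT
        ok = (~fights) | ((aggressor != victim)
                          & ((winner == aggressor) | (winner == victim)))
        if not ok.all():
            line = int(np.flatnonzero(~ok)[0]) + 2
            raise LogFormatError(
                f"line {line}: fight record needs aggressor != victim and winner in {{aggressor, victim}}")
        grooms = event == EVENT_GROOM
        if ((grooms) & (actor == partner)).any():
            line = int(np.flatnonzero(grooms & (actor == partner))[0]) + 2
            raise LogFormatError(f"line {line}: groom record has actor == partner")

        period = df["period"].astype(np.int32).to_numpy()
        index = df["activation_index"].astype(np.int32).to_numpy()
        if activations_per_period is None:
            activations_per_period = int(index.max()) + 1 if len(index) else 0
        run = int(df["run"].iloc[0]) if len(df) else 0
        return cls(run=run, activations_per_period=activations_per_period,
                   burn_in_periods=burn_in_periods, period=period, index=index,
                   event=event, actor=actor.astype(np.int16),
                   partner=partner.astype(np.int16), aggressor=aggressor.astype(np.int16),
                   victim=victim.astype(np.int16), winner=winner.astype(np.int16),
                   x=df["x"].to_numpy(np.float32), y=df["y"].to_numpy(np.float32))


def empty_log(run: int = 0, activations_per_period: int = 500,
              burn_in_periods: int = 0) -> EventLog:
    z16 = np.zeros(0, dtype=np.int16)
    return EventLog(run=run, activations_per_period=activations_per_period,
                    burn_in_periods=burn_in_periods,
                    period=np.zeros(0, np.int32), index=np.zeros(0, np.int32),
                    event=np.zeros(0, np.int8), actor=z16, partner=z16.copy(),
                    aggressor=z16.copy(), victim=z16.copy(), winner=z16.copy(),
                    x=np.zeros(0, np.float32), y=np.zeros(0, np.float32))


def log_from_records(records, run: int, activations_per_period: int,
                     burn_in_periods: int) -> EventLog:
    """Build an EventLog from an iterable of
    (period, index, event, actor, partner, aggressor, victim, winner, x, y)."""
    if len(records) == 0:
        return empty_log(run, activations_per_period, burn_in_periods)
    arr = np.asarray(records, dtype=np.float64)
    return EventLog(
        run=run, activations_per_period=activations_per_period,
        burn_in_periods=burn_in_periods,
        period=arr[:, 0].astype(np.int32), index=arr[:, 1].astype(np.int32),
        event=arr[:, 2].astype(np.int8), actor=arr[:, 3].astype(np.int16),
        partner=arr[:, 4].astype(np.int16), aggressor=arr[:, 5].astype(np.int16),
        victim=arr[:, 6].astype(np.int16), winner=arr[:, 7].astype(np.int16),
        x=arr[:, 8].astype(np.float32), y=arr[:, 9].astype(np.float32))


# --------------------------------------------------------------------------
# Observational-data adapter
# --------------------------------------------------------------------------

#: Default mapping of ethogram acts to the two categories the PC-MC analysis
#: distinguishes.  Shipped as data so users can edit it for their own ethogram.
BEHAVIOUR_CATEGORIES: dict[str, str] = {
    # agonistic acts
    "chase": "agonistic", "lunge": "agonistic", "slap": "agonistic",
    "grab": "agonistic", "bite": "agonistic", "fierce-bite": "agonistic",
    # affiliative acts
    "sit-in-contact": "affiliative", "allogroom": "affiliative",
    "play": "affiliative", "mount": "affiliative", "embrace": "affiliative",
    "touch": "affiliative", "lipsmack": "affiliative",
    "bared-teeth": "affiliative",
}


def observation_block(t_seconds: float, block_seconds: float = 10.0,
                      window_seconds: float = 300.0) -> int | None:
    """10-s block ordinal (1-based) of a contact ``t_seconds`` after the
    window anchor, or None when it falls outside the window."""
    if t_seconds < 0 or t_seconds > window_seconds:
        return None
    return max(1, int(np.ceil(t_seconds / block_seconds)))


def adapt_observations(records: pd.DataFrame, sessions: pd.DataFrame,
                       pc_minutes: float = 5.0, block_seconds: float = 10.0,
                       restart_seconds: float = 30.0,
                       categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Map timestamped field observations onto PC-MC pairs.

    Parameters
    ----------
    records
        One row per observed act: columns ``session`` (identifier),
        ``time_s`` (seconds from session start, non-decreasing per session),
        ``behaviour`` (act name resolved through ``categories``), ``actor``,
        ``receiver``.
    sessions
        One row per PC-MC pair, supplied by the observer (the "next possible
        observation day" matching is an input, not inferred): columns
        ``pair_id``, ``pc_session``, ``mc_session``, ``focal``, ``role``
        (aggressor/victim), ``opponent``.
    Returns a DataFrame with one row per pair and direction, holding the PC
    and MC first-contact blocks and the attracted/dispersed/neutral
    classification, ready for :func:`groofiworld.pcmc.affiliative_tendency`.
    """
    from .pcmc import classify_pair  # late import to avoid a cycle

    categories = BEHAVIOUR_CATEGORIES if categories is None else categories
    window_s = pc_minutes * 60.0
    unknown = set(records["behaviour"]) - set(categories)
    if unknown:
        raise ValueError(f"behaviours missing from the category table: {sorted(unknown)}")
    cat = records["behaviour"].map(categories)

    out = []
    for row in sessions.itertuples(index=False):
        focal, opponent = row.focal, row.opponent
        blocks = {}
        for kind, session in (("pc", row.pc_session), ("mc", row.mc_session)):
            ev = records.loc[records["session"] == session].reset_index(drop=True)
            ev_cat = cat.loc[records["session"] == session].reset_index(drop=True)
            anchor = 0.0
            if kind == "pc":
                # restart on renewed aggression between the same opponents
                pair = {focal, opponent}
                for t, c, a, r in zip(ev["time_s"], ev_cat, ev["actor"], ev["receiver"]):
                    if c == "agonistic" and {a, r} == pair and 0.0 < t - anchor <= restart_seconds:
                        anchor = float(t)
            for direction in ("received", "solicited"):
                first = None
                for t, c, a, r in zip(ev["time_s"], ev_cat, ev["actor"], ev["receiver"]):
                    if c != "affiliative" or t <= anchor:
                        continue
                    if opponent in (a, r):
                        continue  # the former opponent is not a bystander
                    hit = (r == focal) if direction == "received" else (a == focal)
                    if hit:
                        first = observation_block(t - anchor, block_seconds, window_s)
                        break
                blocks[(kind, direction)] = first
        for direction in ("received", "solicited"):
            pc_b, mc_b = blocks[("pc", direction)], blocks[("mc", direction)]
            out.append({"pair_id": row.pair_id, "focal": focal, "role": row.role,
                        "direction": direction, "pc_block": pc_b, "mc_block": mc_b,
                        "classification": classify_pair(pc_b, mc_b)})
    return pd.DataFrame(out)
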