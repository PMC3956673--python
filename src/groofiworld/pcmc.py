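"""PC-MC analysis of post-conflict affiliation.

For every fight in the collection window whose aggressor and/or victim is
female, the focal former opponent is followed through a post-conflict
window (PC) spanning its next three activations, split into three blocks by
those activations; block k covers the events between the focal's (k-1)-th
and k-th activation after the anchor.  The PC restarts when aggression
between the same two opponents recurs before the focal's first activation.
A matched-control window (MC) anchors at the same within-period activation
ordinal of the next period (one period = one observation day) and never
restarts.

Within each window, the first affiliative contact between the focal and a
female bystander (both former opponents excluded) is recorded by direction:
*received* when the bystander grooms the focal, *solicited* when the focal
grooms a bystander.  A PC-MC pair is *attracted* when the first contact came
earlier in PC than in MC, *dispersed* when earlier in MC, and *neutral* on a
tie or when absent from both.  Model logs compare contact times at the
finest resolution available — the elapsed activation count since the window
anchor, the model-time analogue of the empirical 10-s block — while the
coarse 3-block ordinal is retained per pair for audit.  The affiliative
tendency of an individual is

    100 * (attracted - dispersed) / total pairs

reported per role (aggressor/victim) and direction, averaged over the
females with at least one pair, then over runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EVENT_FIGHT, EVENT_GROOM, EventLog

ROLES = ("aggressor", "victim")
DIRECTIONS = ("received", "solicited")


def classify_pair(pc_block, mc_block) -> str:
    """Attracted / dispersed / neutral from the two first-contact blocks
    (None meaning no contact, which compares as +infinity)."""
    pc = np.inf if pc_block is None else pc_block
    mc = np.inf if mc_block is None else mc_block
    if pc < mc:
        return "attracted"
    if mc < pc:
        return "dispersed"
    return "neutral"


def affiliative_tendency(classifications) -> float:
    """100 * (attracted - dispersed) / total; NaN for an empty input
    (a missing value, never zero)."""
    cls = list(classifications)
    if not cls:
        return float("nan")
    a = sum(c == "attracted" for c in cls)
    d = sum(c == "dispersed" for c in cls)
    return 100.0 * (a - d) / len(cls)


class LogIndex:
    """Pre-indexed views of one run's log used by the window machinery."""

    def __init__(self, log: EventLog, females):
        self.log = log
        self.n_events = len(log)
        self.app = log.activations_per_period
        self.females = np.asarray(sorted(females), dtype=int)
        n_ids = int(log.actor.max()) + 1 if len(log) else 0
        self.is_female = np.zeros(max(n_ids, (self.females.max() + 1) if len(self.females) else 0),
                                  dtype=bool)
        self.is_female[self.females] = True

        # clock == row index for simulator logs
        self.act_clocks = {int(i): np.flatnonzero(log.actor == i)
                           for i in range(n_ids)}
        groom_rows = np.flatnonzero(log.event == EVENT_GROOM)
        g_actor = log.actor[groom_rows]
        g_partner = log.partner[groom_rows]
        self.grooms_to = {}
        self.grooms_by = {}
        for f in self.females:
            m_to = g_partner == f
            self.grooms_to[int(f)] = (groom_rows[m_to], g_actor[m_to].astype(int))
            m_by = g_actor == f
            self.grooms_by[int(f)] = (groom_rows[m_by], g_partner[m_by].astype(int))

        fight_rows = np.flatnonzero(log.event == EVENT_FIGHT)
        self.fight_rows = fight_rows
        pair_clocks: dict[tuple[int, int], list[int]] = {}
        for r in fight_rows:
            a, v = int(log.aggressor[r]), int(log.victim[r])
            pair_clocks.setdefault((min(a, v), max(a, v)), []).append(int(r))
        self.pair_clocks = {k: np.asarray(v) for k, v in pair_clocks.items()}

    def next_activations(self, focal: int, anchor: int, k: int = 3):
        acts = self.act_clocks.get(focal)
        if acts is None:
            return None
        lo = np.searchsorted(acts, anchor, side="right")
        if lo + k > len(acts):
            return None
        return acts[lo:lo + k]


@dataclass
class Conflict:
    clock: int
    aggressor: int
    victim: int
    focal: int
    role: str


def extract_conflicts(log: EventLog, females) -> list[Conflict]:
    """One conflict per collection-window fight per female opponent (each
    female opponent is followed separately)."""
    female_set = set(int(f) for f in females)
    rows = np.flatnonzero((log.event == EVENT_FIGHT) & log.collected)
    out = []
    for r in rows:
        a, v = int(log.aggressor[r]), int(log.victim[r])
        if a in female_set:
            out.append(Conflict(int(r), a, v, a, "aggressor"))
        if v in female_set:
            out.append(Conflict(int(r), a, v, v, "victim"))
    return out


def build_pc_window(index: LogIndex, conflict: Conflict):
    """PC window (anchor, a1, a2, a3) for the focal, restarting at renewed
    aggression between the same opponents before the focal's first
    activation; None when fewer than three focal activations remain."""
    pair = (min(conflict.aggressor, conflict.victim),
            max(conflict.aggressor, conflict.victim))
    pair_rows = index.pair_clocks.get(pair)
    anchor = conflict.clock
    while True:
        acts = index.next_activations(conflict.focal, anchor)
        if acts is None:
            return None
        lo = np.searchsorted(pair_rows, anchor, side="right")
        if lo < len(pair_rows) and pair_rows[lo] <= acts[0]:
            anchor = int(pair_rows[lo])  # aggression recurred in block 1: restart
            continue
        return (anchor, int(acts[0]), int(acts[1]), int(acts[2]))


def build_mc_window(index: LogIndex, conflict: Conflict):
    """MC window anchored at the same within-period activation ordinal of
    the next period; no restart rule.  None when the conflict falls in the
    final period or fewer than three focal activations remain."""
    mc_anchor = conflict.clock + index.app
    if mc_anchor >= index.n_events:
        return None
    acts = index.next_activations(conflict.focal, mc_anchor)
    if acts is None:
        return None
    return (mc_anchor, int(acts[0]), int(acts[1]), int(acts[2]))


def first_contact_block(index: LogIndex, window, focal: int, direction: str,
                        opponents) -> int | None:
    """Block (1..3) of the first focal-bystander groom inside the window, or
    None.  Bystanders are females excluding both opponents of the conflict."""
    contacts = window_contacts(index, window, focal, direction, opponents)
    return contacts[0][1] if contacts else None


def window_contacts(index: LogIndex, window, focal: int, direction: str,
                    opponents) -> list[tuple[int, int, int]]:
    """All (bystander, block, offset) focal-bystander grooms inside the
    window, in clock order.  ``block`` is the coarse ordinal (which focal
    inter-activation gap held the contact); ``offset`` is the fine position,
    in elapsed activations since the window anchor — the model-time analogue
    of the empirical 10-s block."""
    anchor, a1, a2, a3 = window
    store = index.grooms_to if direction == "received" else index.grooms_by
    clocks, others = store[int(focal)]
    lo = np.searchsorted(clocks, anchor, side="right")
    hi = np.searchsorted(clocks, a3, side="right")
    out = []
    o1, o2 = opponents
    for c, other in zip(clocks[lo:hi], others[lo:hi]):
        if other == o1 or other == o2 or not index.is_female[other]:
            continue
        out.append((int(other), 1 + (c > a1) + (c > a2), int(c - anchor)))
    return out


@dataclass
class PCMCResult:
    """Per-pair ledger plus window contact counts for one run."""

    pairs: pd.DataFrame      # one row per (conflict, focal, direction)
    contacts: pd.DataFrame   # every PC-window focal-bystander groom
    windows: pd.DataFrame    # every valid (conflict, focal) PC window
    n_dropped: int           # conflicts dropped for incomplete PC or MC


def analyze_log(log: EventLog, females) -> PCMCResult:
    """Run the full PC-MC pipeline on one log."""
    index = LogIndex(log, females)
    pairs, contacts, windows = [], [], []
    dropped = 0
    for conflict in extract_conflicts(log, females):
        pc = build_pc_window(index, conflict)
        mc = build_mc_window(index, conflict)
        if pc is None or mc is None:
            dropped += 1
            continue
        opponents = (conflict.aggressor, conflict.victim)
        windows.append((conflict.clock, conflict.focal, conflict.role,
                        conflict.aggressor, conflict.victim, *pc))
        for direction in DIRECTIONS:
            pc_contacts = window_contacts(index, pc, conflict.focal, direction, opponents)
            mc_contacts = window_contacts(index, mc, conflict.focal, direction, opponents)
            pc_block = pc_contacts[0][1] if pc_contacts else None
            mc_block = mc_contacts[0][1] if mc_contacts else None
            pc_off = pc_contacts[0][2] if pc_contacts else None
            mc_off = mc_contacts[0][2] if mc_contacts else None
            pairs.append((conflict.clock, conflict.focal, conflict.role, direction,
                          pc_block, mc_block, pc_off, mc_off,
                          classify_pair(pc_off, mc_off)))
            for bystander, block, _ in pc_contacts:
                contacts.append((conflict.focal, conflict.role, direction,
                                 bystander, block))
    pairs_df = pd.DataFrame(pairs, columns=["conflict_clock", "focal", "role",
                                            "direction", "pc_block", "mc_block",
                                            "pc_offset", "mc_offset",
                                            "classification"])
    contacts_df = pd.DataFrame(contacts, columns=["focal", "role", "direction",
                                                  "bystander", "block"])
    windows_df = pd.DataFrame(windows, columns=["conflict_clock", "focal", "role",
                                                "aggressor", "victim", "anchor",
                                                "a1", "a2", "a3"])
    return PCMCResult(pairs_df, contacts_df, windows_df, dropped)


# --------------------------------------------------------------------------
# Tendency tables
# --------------------------------------------------------------------------

def tendency_by_individual(pairs: pd.DataFrame, females) -> pd.DataFrame:
    """Per-female tendencies for the role x direction strata (females without
    pairs in a stratum are simply absent from it)."""
    rows = []
    for (role, direction), grp in pairs.groupby(["role", "direction"]):
        for focal, sub in grp.groupby("focal"):
            rows.append((int(focal), role, direction, len(sub),
                         affiliative_tendency(sub["classification"])))
    return pd.DataFrame(rows, columns=["focal", "role", "direction", "n_pairs",
                                       "tendency"])


def tendency_table(pairs: pd.DataFrame, females) -> pd.DataFrame:
    """Group-mean tendencies (mean over females with >= 1 pair) for the
    2x2 of role x direction, from one run's pairs."""
    ind = tendency_by_individual(pairs, females)
    rows = []
    for role in ROLES:
        for direction in DIRECTIONS:
            sub = ind[(ind.role == role) & (ind.direction == direction)]
            rows.append((role, direction,
                         float(sub["tendency"].mean()) if len(sub) else float("nan"),
                         int(sub["n_pairs"].sum())))
    return pd.DataFrame(rows, columns=["role", "direction", "tendency", "n_pairs"])


def mean_tendencies(per_run_pairs: list[pd.DataFrame], females) -> dict[tuple[str, str], float]:
    """Cross-run means: each run contributes its group-mean tendency."""
    acc: dict[tuple[str, str], list[float]] = {(r, d): [] for r in ROLES for d in DIRECTIONS}
    for pairs in per_run_pairs:
        tab = tendency_table(pairs, females)
        for row in tab.itertuples(index=False):
            if np.isfinite(row.tendency):
                acc[(row.role, row.direction)].append(row.tendency)
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in acc.items()}


def pooled_individual_tendencies(per_run_pairs: list[pd.DataFrame], females) -> pd.DataFrame:
    """Per-female tendencies with the PC-MC pairs of all runs pooled
    (the basis of the received-vs-solicited matched comparison)."""
    pooled = pd.concat(per_run_pairs, ignore_index=True)
    return tendency_by_individual(pooled, females)
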