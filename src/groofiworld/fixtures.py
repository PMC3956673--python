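"""Synthetic event logs with planted post-conflict structure.

These fixtures exercise the PC-MC bookkeeping without the spatial
simulator: activations follow a round-robin schedule with per-cycle jitter,
fights occur at a fixed per-activation rate between random females, and a
known attraction effect is planted by converting, with the configured
probability, one bystander activation in PC block 1 into a groom of the
focal (received) and/or the focal's first post-fight activation into a
groom of a bystander (solicited).  Elsewhere grooming happens at the same
background rate inside and outside windows, so the matched control is a
true control and closed-form expected tendencies exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import (EVENT_FIGHT, EVENT_GROOM, EVENT_MOVE, NONE_ID, EventLog)


@dataclass
class FixtureParams:
    n_females: int = 14
    n_periods: int = 150
    activations_per_period: int = 140
    fight_rate: float = 0.01
    p_attract_received: float = 0.0
    p_attract_solicited: float = 0.0
    background_groom_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("fight_rate", "p_attract_received", "p_attract_solicited",
                     "background_groom_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fight_rate + self.background_groom_rate > 1.0:
            raise ValueError("fight_rate + background_groom_rate imply more than "
                             "one event per activation")
        if self.n_females < 3:
            raise ValueError("need at least 3 females for bystanders to exist")


def generate_planted_log(params: FixtureParams) -> EventLog:
    """Synthetic log satisfying every event-record invariant, with known
    attraction effects planted in PC block 1."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_females
    total = params.n_periods * params.activations_per_period

    # round-robin schedule with per-cycle jitter
    n_cycles = math.ceil(total / n)
    actors = np.concatenate([rng.permutation(n) for _ in range(n_cycles)])[:total]
    act_slots = {i: np.flatnonzero(actors == i) for i in range(n)}

    event = np.full(total, EVENT_MOVE, dtype=np.int8)
    partner = np.full(total, NONE_ID, dtype=np.int16)
    aggressor = np.full(total, NONE_ID, dtype=np.int16)
    victim = np.full(total, NONE_ID, dtype=np.int16)
    winner = np.full(total, NONE_ID, dtype=np.int16)

    u = rng.random(total)
    fight_slots = np.flatnonzero(u < params.fight_rate)
    groom_slots = np.flatnonzero(
        (u >= params.fight_rate)
        & (u < params.fight_rate + params.background_groom_rate))

    others = rng.integers(0, n - 1, size=total)
    for t in fight_slots:
        a = actors[t]
        v = others[t] + (others[t] >= a)
        event[t] = EVENT_FIGHT
        partner[t] = v
        aggressor[t], victim[t] = a, v
        winner[t] = a if rng.random() < 0.5 else v
    for t in groom_slots:
        a = actors[t]
        event[t] = EVENT_GROOM
        partner[t] = others[t] + (others[t] >= a)

    # Plant attraction effects in PC block 1 of each fight's two focals.
    # Planted slots are reserved so plants of different focals never collide;
    # if block 1 offers no free bystander slot the plant falls back to blocks
    # 2-3 (still earlier than any MC-only contact, so the classification is
    # unchanged in the zero-background regime).
    used: set[int] = set()

    def _bystander_slots(lo: int, hi: int, a: int, v: int) -> np.ndarray:
        sl = np.arange(lo, hi)
        ok = sl[(actors[sl] != a) & (actors[sl] != v) & (event[sl] != EVENT_FIGHT)]
        return np.array([s for s in ok if s not in used], dtype=int)

    for t in fight_slots:
        a, v = int(aggressor[t]), int(victim[t])
        for focal in (a, v):
            slots = act_slots[focal]
            k = np.searchsorted(slots, t, side="right")
            if k >= len(slots):
                continue
            a1 = int(slots[k])
            a3 = int(slots[k + 2]) if k + 2 < len(slots) else total - 1
            if params.p_attract_received and rng.random() < params.p_attract_received:
                ok = _bystander_slots(t + 1, a1 + 1, a, v)
                if len(ok) == 0:
                    ok = _bystander_slots(a1 + 1, a3 + 1, a, v)
                if len(ok):
                    s = int(rng.choice(ok))
                    used.add(s)
                    event[s] = EVENT_GROOM
                    partner[s] = focal
            if params.p_attract_solicited and rng.random() < params.p_attract_solicited:
                if event[a1] != EVENT_FIGHT and a1 not in used:
                    used.add(a1)
                    bystanders = [b for b in range(n) if b not in (a, v)]
                    event[a1] = EVENT_GROOM
                    partner[a1] = int(rng.choice(bystanders))

    clocks = np.arange(total, dtype=np.int64)
    app = params.activations_per_period
    return EventLog(run=1, activations_per_period=app, burn_in_periods=0,
                    period=(clocks // app + 1).astype(np.int32),
                    index=(clocks % app).astype(np.int32),
                    event=event, actor=actors.astype(np.int16), partner=partner,
                    aggressor=aggressor, victim=victim, winner=winner,
                    x=np.zeros(total, np.float32), y=np.zeros(total, np.float32))


# --------------------------------------------------------------------------
# Closed-form expectations
# --------------------------------------------------------------------------

def _first_contact_distribution(no_contact_per_block) -> list[float]:
    """P(first contact in block 1..3, or never) from per-block no-contact
    probabilities."""
    out = []
    alive = 1.0
    for s in no_contact_per_block:
        out.append(alive * (1.0 - s))
        alive *= s
    out.append(alive)
    return out


def _expected_from_blocks(pc_nc, mc_nc) -> float:
    p = _first_contact_distribution(pc_nc)
    q = _first_contact_distribution(mc_nc)
    blocks = [1, 2, 3, np.inf]
    attracted = dispersed = 0.0
    for i, bp in enumerate(blocks):
        for j, bq in enumerate(blocks):
            if bp < bq:
                attracted += p[i] * q[j]
            elif bq < bp:
                dispersed += p[i] * q[j]
    return 100.0 * (attracted - dispersed)


def expected_tendency(params: FixtureParams) -> dict[str, float]:
    """Analytic expectation of the affiliative tendency under the fixture.

    With zero background the planted direction's tendency is exactly
    100 * p_attract and the other direction 0.  With background b > 0 the
    expectation follows the first-contact race between PC and MC blocks,
    treating each block as holding one activation per non-focal individual
    (exact for the jittered round-robin on average; accurate while
    b and fight_rate are small, say below ~0.05, since overlapping windows
    and planted grooms of other conflicts are ignored).
    """
    params.validate()
    n = params.n_females
    b = params.background_groom_rate

    # received: n-2 eligible bystander activations per block
    q_recv = b / (n - 1)
    s_recv = (1.0 - q_recv) ** (n - 2)
    pc_nc = [(1.0 - params.p_attract_received) * s_recv, s_recv, s_recv]
    mc_nc = [s_recv, s_recv, s_recv]
    t_received = _expected_from_blocks(pc_nc, mc_nc)

    # solicited: one focal activation per block
    c_sol = b * (n - 2) / (n - 1)
    s_sol = 1.0 - c_sol
    pc_nc = [(1.0 - params.p_attract_solicited) * s_sol, s_sol, s_sol]
    mc_nc = [s_sol, s_sol, s_sol]
    t_solicited = _expected_from_blocks(pc_nc, mc_nc)

    return {"received": t_received, "solicited": t_solicited}
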