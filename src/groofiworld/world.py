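"""Spatial world, activation schedule and main simulation loop.

Individuals live on an unbounded continuous plane.  Each carries an
activation timer; the individual with the smallest timer acts next, all
other timers shrink by the elapsed wait, and the actor redraws its timer
uniformly from (0, 1].  Social facilitation makes individuals close to a
fight act sooner: their current timers shrink by a factor < 1 and their
next few redraws stay shortened (a brief arousal state) — the
activation-timing mechanism behind received post-conflict affiliation.

On activation an individual interacts with a partner drawn uniformly among
those within ``per_space`` (fight if the mental battle says attack, else
maybe groom), or otherwise follows the grouping rule: keep course while at
least ``min_near_neighbors`` others are within ``near_view``, else turn
toward the centroid of the individuals within ``max_view``, or rotate by
the search angle when alone.
"""

from __future__ import annotations

import math

import numpy as np

from .config import SimConfig
from .io import (EVENT_FIGHT, EVENT_GROOM, EVENT_MOVE, EVENT_SEARCH, NONE_ID,
                 EventLog)
from .rules import (attack_probability, clamp01, update_dominance, win_chance)


class World:
    """Mutable world state for one run: positions, headings, dominance,
    anxiety, grooming motivation and activation timers, plus the event log
    buffers.  Fully deterministic given (config, initial dominance, seed)."""

    def __init__(self, config: SimConfig, initial_dominance, seed: int, run_id: int = 1):
        config.validate()
        n = config.n_individuals
        dom = np.asarray(initial_dominance, dtype=np.float64)
        if dom.shape != (n,):
            raise ValueError(
                f"initial dominance vector has length {dom.size}, expected {n}")
        if not (dom > 0).all():
            raise ValueError("initial dominance values must be positive")

        self.config = config
        self.run_id = run_id
        self.n = n
        self.rng = np.random.default_rng(seed)
        self.female = np.zeros(n, dtype=bool)
        self.female[: config.n_females] = True  # ids 0..n_females-1 are female

        half = config.start_square / 2.0
        self.pos = self.rng.uniform(-half, half, size=(n, 2))
        self.heading = self.rng.uniform(0.0, 2.0 * math.pi, size=n)
        self.dominance = dom.copy()
        self.anxiety = np.full(n, config.anxiety.baseline)
        self.motivation = np.zeros(n)
        self.timer = 1.0 - self.rng.random(n)  # (0, 1]
        self.arousal = np.zeros(n, dtype=np.int32)  # boosted redraws left
        self.groomed_since_last = np.zeros(n, dtype=bool)
        self.clock = 0

        # event buffers
        total = config.n_periods * config.activations_per_period
        self._ev_event = np.zeros(total, dtype=np.int8)
        self._ev_actor = np.zeros(total, dtype=np.int16)
        self._ev_partner = np.full(total, NONE_ID, dtype=np.int16)
        self._ev_agg = np.full(total, NONE_ID, dtype=np.int16)
        self._ev_vct = np.full(total, NONE_ID, dtype=np.int16)
        self._ev_win = np.full(total, NONE_ID, dtype=np.int16)
        self._ev_x = np.zeros(total, dtype=np.float32)
        self._ev_y = np.zeros(total, dtype=np.float32)

        # cached scalars for the hot loop
        c = config
        self._per2 = c.per_space ** 2
        self._near2 = c.near_view ** 2
        self._max2 = c.max_view ** 2
        self._min_near = c.min_near_neighbors
        self._fac_rad2 = c.social_facilitation_radius ** 2
        self._fac = 1.0 if c.variant == "no_social_facilitation" else c.facilitation_factor
        self._search_rad = math.radians(c.search_angle)
        self._step_f = c.aggression_intensity_female
        self._step_m = c.aggression_intensity_male
        self._risk = c.risk_exponent
        self._random_partners = c.variant == "random_partners"
        self._gate = c.interaction_gate
        self._anx_increment = (0.0 if c.variant == "no_anxiety_increase"
                               else c.anxiety.fight_increment)
        self._const_groom = c.variant == "anxiety_independent_grooming"

    # ------------------------------------------------------------ scheduling

    def schedule_next(self) -> int:
        """Activate the individual with the minimum timer.

        All timers decrease by the elapsed minimum; the activated individual
        redraws its timer uniformly from (0, 1].  Ties break to the lowest id
        (numpy argmin convention).
        """
        timer = self.timer
        i = int(np.argmin(timer))
        timer -= timer[i]
        draw = 1.0 - self.rng.random()
        if self.arousal[i] > 0:
            draw *= self._fac
            self.arousal[i] -= 1
        timer[i] = draw
        return i

    def apply_social_facilitation(self, location, opponents) -> None:
        """Shrink the activation timers of all non-opponents within the
        facilitation radius of ``location`` by the facilitation factor."""
        if self._fac >= 1.0:
            return
        d = self.pos - location
        near = d[:, 0] ** 2 + d[:, 1] ** 2 <= self._fac_rad2
        near[list(opponents)] = False
        self.timer[near] *= self._fac
        self.arousal[near] = self.config.facilitation_boost_draws

    def perceive(self, i: int):
        """(nearest within PerSpace or None, anyone within NearView?,
        nearest within MaxView or None); Euclidean, ties to lowest id."""
        d = self.pos - self.pos[i]
        d2 = d[:, 0] ** 2 + d[:, 1] ** 2
        d2[i] = np.inf
        j = int(np.argmin(d2))
        nearest2 = d2[j]
        return (j if nearest2 <= self._per2 else None,
                bool((d2 <= self._near2).any()),
                j if nearest2 <= self._max2 else None)

    # ------------------------------------------------------------- main loop

    def step(self) -> int:
        """One activation: schedule, act, record exactly one event, decay.
        Returns the id of the activated individual."""
        cfg = self.config
        rng = self.rng
        pos = self.pos
        i = self.schedule_next()
        t = self.clock

        d = pos - pos[i]
        d2 = d[:, 0] ** 2 + d[:, 1] ** 2
        d2[i] = np.inf
        j = int(np.argmin(d2))
        nearest2 = d2[j]

        if nearest2 <= self._per2 and (self._gate >= 1.0 or rng.random() < self._gate):
            if self._random_partners:
                j = int(rng.integers(self.n - 1))
                if j >= i:
                    j += 1
            else:
                # interaction partner: uniform among all within PerSpace
                cand = np.flatnonzero(d2 <= self._per2)
                if len(cand) > 1:
                    j = int(cand[rng.integers(len(cand))])
            p_attack = attack_probability(self.dominance[i], self.dominance[j], self._risk)
            if rng.random() < p_attack:
                self._resolve_fight(i, j, t, d2)
            else:
                if self._const_groom:
                    p_groom = cfg.p_groom_const
                else:
                    p_groom = min(1.0, cfg.groom_rate_scale * (self.anxiety[i] + self.motivation[i]))
                if rng.random() < p_groom:
                    self._apply_grooming(i, j, t)
                else:
                    self._ev_event[t] = EVENT_MOVE
                    self._ev_actor[t] = i
                    self._ev_x[t], self._ev_y[t] = pos[i]
        else:
            in_near = d2 <= self._near2
            if int(in_near.sum()) >= self._min_near:
                pass  # enough of the group close by: stay on course
            elif nearest2 <= self._max2:
                # drifting out: turn toward the centroid of visible others
                in_max = d2 <= self._max2
                cx = pos[in_max, 0].mean() - pos[i, 0]
                cy = pos[in_max, 1].mean() - pos[i, 1]
                if cx * cx + cy * cy > 1e-12:
                    self.heading[i] = math.atan2(cy, cx)
            else:
                self.heading[i] += self._search_rad if rng.random() < 0.5 else -self._search_rad
                self._ev_event[t] = EVENT_SEARCH
                self._ev_actor[t] = i
                self._ev_x[t], self._ev_y[t] = pos[i]
                self._after_step(i, t)
                return i
            h = self.heading[i]
            pos[i, 0] += cfg.move_step * math.cos(h)
            pos[i, 1] += cfg.move_step * math.sin(h)
            self._ev_event[t] = EVENT_MOVE
            self._ev_actor[t] = i
            self._ev_x[t], self._ev_y[t] = pos[i]

        self._after_step(i, t)
        return i

    def _after_step(self, i: int, t: int) -> None:
        anx = self.anxiety
        a = self.config.anxiety
        anx[i] = clamp01(anx[i] + a.decay_rate * (a.baseline - anx[i]))
        if self.groomed_since_last[i]:
            self.groomed_since_last[i] = False
        else:
            self.motivation[i] += a.motivation_increment
        self.clock = t + 1

    def _resolve_fight(self, i: int, j: int, t: int, d2) -> None:
        if i == j:
            raise ValueError("an individual cannot fight itself")
        rng = self.rng
        pos = self.pos
        w = win_chance(self.dominance[i], self.dominance[j])
        i_won = rng.random() < w
        step = self._step_f if self.female[i] else self._step_m
        self.dominance[i], self.dominance[j] = update_dominance(
            self.dominance[i], self.dominance[j], i_won, step)

        location = (pos[i] + pos[j]) / 2.0
        winner, loser = (i, j) if i_won else (j, i)
        u = pos[loser] - pos[winner]
        norm = math.hypot(u[0], u[1])
        if norm < 1e-12:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            u = np.array([math.cos(ang), math.sin(ang)])
        else:
            u = u / norm
        ang = math.atan2(u[1], u[0])
        cfg = self.config
        self.heading[winner] = ang
        self.heading[loser] = ang  # turned away from the winner
        pos[winner] += cfg.chase_distance * u
        pos[loser] += cfg.flee_distance * u

        if self._anx_increment:
            self.anxiety[i] = clamp01(self.anxiety[i] + self._anx_increment)
            self.anxiety[j] = clamp01(self.anxiety[j] + self._anx_increment)

        self._ev_event[t] = EVENT_FIGHT
        self._ev_actor[t] = i
        self._ev_partner[t] = j
        self._ev_agg[t] = i
        self._ev_vct[t] = j
        self._ev_win[t] = winner
        self._ev_x[t], self._ev_y[t] = location

        # facilitation happens on the same clock tick as the fight
        self.apply_social_facilitation(location, (i, j))

    def _apply_grooming(self, i: int, j: int, t: int) -> None:
        a = self.config.anxiety
        self.anxiety[j] = clamp01(self.anxiety[j] * (1.0 - a.reduction_received))
        self.anxiety[i] = clamp01(self.anxiety[i] * (1.0 - a.reduction_given))
        self.motivation[i] = 0.0
        self.motivation[j] = 0.0
        self.groomed_since_last[j] = True
        self._ev_event[t] = EVENT_GROOM
        self._ev_actor[t] = i
        self._ev_partner[t] = j
        self._ev_x[t], self._ev_y[t] = self.pos[i]

    # ---------------------------------------------------------------- output

    def run(self) -> EventLog:
        total = self.config.n_periods * self.config.activations_per_period
        while self.clock < total:
            self.step()
        return self.event_log()

    def event_log(self) -> EventLog:
        cfg = self.config
        t = self.clock
        app = cfg.activations_per_period
        clocks = np.arange(t, dtype=np.int64)
        return EventLog(
            run=self.run_id, activations_per_period=app,
            burn_in_periods=cfg.burn_in_periods,
            period=(clocks // app + 1).astype(np.int32),
            index=(clocks % app).astype(np.int32),
            event=self._ev_event[:t].copy(), actor=self._ev_actor[:t].copy(),
            partner=self._ev_partner[:t].copy(), aggressor=self._ev_agg[:t].copy(),
            victim=self._ev_vct[:t].copy(), winner=self._ev_win[:t].copy(),
            x=self._ev_x[:t].copy(), y=self._ev_y[:t].copy())

    def mean_nearest_neighbour_distance(self) -> float:
        d = self.pos[:, None, :] - self.pos[None, :, :]
        d2 = (d ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min(axis=1)).mean())


def init_world(config: SimConfig, initial_dominance, seed: int, run_id: int = 1) -> World:
    """Place individuals uniformly in the starting square with random
    headings, baseline anxiety, fresh timers and an empty log."""
    return World(config, initial_dominance, seed, run_id)


def run_simulation(config: SimConfig, initial_dominance=None, seed: int | None = None,
                   run_id: int = 1) -> EventLog:
    """Execute one full run (n_periods x activations_per_period activations)
    and return its event log; deterministic given (config, seed)."""
    if initial_dominance is None:
        from .experiments import default_dominance
        initial_dominance = default_dominance(config)
    if seed is None:
        seed = config.seed
    return World(config, initial_dominance, seed, run_id=run_id).run()


def run_replicas(config: SimConfig, n_runs: int | None = None,
                 initial_dominance=None) -> list[EventLog]:
    """Independent replicas differing only by seed (derived as [seed, run])."""
    if n_runs is None:
        n_runs = config.n_runs
    logs = []
    for r in range(1, n_runs + 1):
        seed = int(np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2 ** 31))
        logs.append(run_simulation(config, initial_dominance=initial_dominance,
                                   seed=seed, run_id=r))
    return logs
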