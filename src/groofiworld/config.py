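"""Run configuration: model parameters, variant switches, seeds.

A :class:`SimConfig` is the single source of truth for a simulation run.
Defaults describe a tolerant macaque-like group: 25 individuals (14 females,
11 males), low intensity of aggression, grooming calibrated to occur about
four times as often as fighting, and a shallow dominance hierarchy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

VARIANTS = (
    "complete",
    "no_social_facilitation",
    "random_partners",
    "no_anxiety_increase",
    "anxiety_independent_grooming",
)


@dataclass
class AnxietyParams:
    """Anxiety and grooming-motivation dynamics.

    Anxiety lives in [0, 1] and relaxes toward ``baseline`` by a fraction
    ``decay_rate`` of the gap at each of the individual's own activations.
    Fighting raises both opponents' anxiety by ``fight_increment``; being
    groomed shrinks anxiety by the fraction ``reduction_received`` and
    grooming someone else by the smaller fraction ``reduction_given``.
    Motivation to groom accrues by ``motivation_increment`` per activation
    while the individual has not been groomed, and resets to zero after
    giving or receiving grooming.
    """

    baseline: float = 0.25
    fight_increment: float = 0.15
    reduction_received: float = 0.5
    reduction_given: float = 0.1
    decay_rate: float = 0.05
    motivation_increment: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("anxiety baseline must lie in [0, 1]")
        if self.fight_increment <= 0:
            raise ValueError("fight_increment must be positive")
        if not self.reduction_received > self.reduction_given:
            raise ValueError(
                "receiving grooming must reduce anxiety more than giving it "
                "(reduction_received > reduction_given)"
            )
        for name in ("reduction_received", "reduction_given"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class SimConfig:
    """All model parameters for one simulation study.

    Distances are in world units (an individual moves ``move_step`` units per
    travelling activation); angles in degrees; times in activations.
    """

    # group composition
    n_individuals: int = 25
    n_females: int = 14
    n_males: int = 11

    # dominance interactions
    aggression_intensity_female: float = 0.08
    aggression_intensity_male: float = 0.10
    risk_exponent: float = 4.0  # mental battle: P(attack) = win_chance ** k
    initial_dominance_min: float = 8.0
    initial_dominance_max: float = 24.0

    # perception and movement
    per_space: float = 3.0
    near_view: float = 5.0
    max_view: float = 50.0
    min_near_neighbors: int = 8
    search_angle: float = 90.0
    move_step: float = 1.0
    flee_distance: float = 0.5
    chase_distance: float = 0.25
    start_square: float = 10.0

    # social facilitation
    social_facilitation_radius: float = 4.0
    facilitation_factor: float = 0.02
    facilitation_boost_draws: int = 4  # redraws kept short while aroused

    # anxiety / grooming
    anxiety: AnxietyParams = field(default_factory=AnxietyParams)
    groom_rate_scale: float = 1.68  # g0, calibrated to groom:fight = 4:1
    p_groom_const: float = 0.325  # used only by anxiety_independent_grooming
    # fraction of perceived encounters that become interactions; used by the
    # random_partners variant to keep the interaction volume per individual
    # at the complete model's level
    interaction_gate: float = 1.0

    # schedule
    n_periods: int = 350
    burn_in_periods: int = 200
    n_runs: int = 10
    seed: int = 1
    variant: str = "complete"

    @property
    def activations_per_period(self) -> int:
        return 20 * self.n_individuals

    @property
    def n_collected_periods(self) -> int:
        return self.n_periods - self.burn_in_periods

    def validate(self) -> None:
        if self.n_females + self.n_males != self.n_individuals:
            raise ValueError("n_females + n_males must equal n_individuals")
        if not 0.0 < self.per_space < self.near_view < self.max_view:
            raise ValueError("perception ranges must satisfy 0 < PerSpace < NearView < MaxView")
        if not 0.0 < self.facilitation_factor <= 1.0:
            raise ValueError("facilitation_factor must lie in (0, 1]")
        if not self.burn_in_periods < self.n_periods:
            raise ValueError("burn_in_periods must be smaller than n_periods")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.risk_exponent <= 0:
            raise ValueError("risk_exponent must be positive")
        if self.groom_rate_scale < 0 or not 0.0 <= self.p_groom_const <= 1.0:
            raise ValueError("grooming parameters out of range")
        if not 0.0 < self.interaction_gate <= 1.0:
            raise ValueError("interaction_gate must lie in (0, 1]")
        self.anxiety.validate()

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        anx = d.pop("anxiety", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d, anxiety=AnxietyParams(**anx))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "SimConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg
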