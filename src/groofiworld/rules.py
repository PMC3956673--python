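"""Behavioural rules: risk-sensitive fighting and anxiety-driven grooming.

The winner-loser effect is self-reinforcing: winning raises and losing
lowers an individual's capacity to win future fights, with upsets moving
dominance more than expected outcomes (damped positive feedback).  Whether
an individual attacks at all is decided by a "mental battle": it only
attacks when it judges itself likely to win, with a risk-sensitivity
exponent that suppresses attacks in uncertain contests.  Individuals that
decline to fight may groom instead, the more readily the more anxious they
are; grooming reduces anxiety, more for the receiver than for the groomer.
"""

from __future__ import annotations

import math

DOMINANCE_FLOOR = 0.01  # epsilon clamp keeping dominance positive


def win_chance(d_i: float, d_j: float) -> float:
    """Probability that ``i`` beats ``j``: relative dominance D_i/(D_i+D_j)."""
    if d_i <= 0 or d_j <= 0:
        raise ValueError("dominance values must be positive")
    return d_i / (d_i + d_j)


def attack_probability(d_i: float, d_j: float, risk_exponent: float = 1.0) -> float:
    """P(attack) = win_chance ** k.

    ``k = 1`` means individuals attack exactly as often as they expect to
    win; ``k > 1`` makes them risk-averse, rarely attacking in contests they
    could easily lose.  Strictly increasing in the chance of winning.
    """
    return win_chance(d_i, d_j) ** risk_exponent


def decide_attack(d_i: float, d_j: float, rng, risk_exponent: float = 1.0) -> bool:
    """Mental battle: draw u ~ U(0,1), attack iff P(attack) > u."""
    return rng.random() < attack_probability(d_i, d_j, risk_exponent)


def update_dominance(d_i: float, d_j: float, i_won: bool, step: float) -> tuple[float, float]:
    """Self-reinforcing winner-loser update.

    With w the pre-fight chance that ``i`` wins and o the outcome (1 if
    ``i`` won), ``i`` gains ``step * (o - w)`` and ``j`` loses the same, so
    the total is conserved and unexpected outcomes move values the most.
    Values are clamped at a small positive floor.
    """
    if step <= 0:
        raise ValueError("dominance step size must be positive")
    w = win_chance(d_i, d_j)
    delta = step * ((1.0 if i_won else 0.0) - w)
    return (max(DOMINANCE_FLOOR, d_i + delta), max(DOMINANCE_FLOOR, d_j - delta))


def groom_probability(anxiety: float, motivation: float, g0: float) -> float:
    """clamp(g0 * (anxiety + motivation), 0, 1): the more anxious (and the
    longer ungroomed), the more inclined to groom."""
    if not 0.0 <= anxiety <= 1.0:
        raise ValueError("anxiety must lie in [0, 1]")
    if motivation < 0:
        raise ValueError("motivation must be non-negative")
    return min(1.0, max(0.0, g0 * (anxiety + motivation)))


def grooming_anxiety_updates(groomer_anxiety: float, groomee_anxiety: float,
                             reduction_given: float, reduction_received: float
                             ) -> tuple[float, float]:
    """Anxiety after a grooming bout: the receiver's anxiety shrinks by the
    larger fraction, the groomer's by the smaller one."""
    return (groomer_anxiety * (1.0 - reduction_given),
            groomee_anxiety * (1.0 - reduction_received))


def decay_anxiety(anxiety: float, baseline: float, decay_rate: float) -> float:
    """Relax anxiety toward baseline by ``decay_rate`` of the current gap."""
    return anxiety + decay_rate * (baseline - anxiety)


def clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def wrap_angle(a: float) -> float:
    return math.atan2(math.sin(a), math.cos(a))
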