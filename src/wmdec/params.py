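"""Model parameters and statistical-subject sampling.

The architecture runs on a fixed set of quantitative parameters (activation
growth and inhibition rates, store capacities, decay rates, motor thresholds).
Inter-subject variability is produced by resampling six of them per simulated
("statistical") subject from a clipped gaussian centred on the standard value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from random import Random


@dataclass
class ModelParameters:
    """Standard parameter settings of the architecture.

    Rates are per 10-ms cycle.  ``alpha``..``zeta`` follow the standard
    working-memory notation: activation growth (alpha), lateral inhibition
    (beta), initial instance activation (phi), inhibition of rejected traces
    (tau), phonological decay (delta), rehearsal/revival growth (rho), visual
    decay (sigma), rule learning (eta), episodic consolidation (kappa),
    response threshold (theta), response noise sd (lambda), drift means (zeta).
    """

    alpha: float = 0.02          # EB/EM activation growth rate
    beta: float = 0.99           # lateral inhibition rate
    phi: float = 0.25            # initial activation of a new instance
    tau: float = 0.75            # inhibition rate of rejected instances
    eb_capacity: float = 2.90    # episodic-buffer activation capacity
    em_capacity: float = 5.0     # executive-memory activation capacity
    delta: float = 0.989         # phonological decay rate
    rho: float = 0.10            # rehearsal / revival growth rate
    sigma: float = 0.99          # visuospatial decay rate
    eta: float = 0.00008         # production-rule learning rate
    kappa: float = 0.001         # episodic-LTM consolidation rate
    theta: float = 0.50          # response threshold (neutral)
    lam: float = 0.01            # sd of gaussian response-production noise
    zeta: float = 0.015          # drift mean, intentional response stream
    zeta_auto: float = 0.004     # drift mean, automatic response stream
    syllable_cycles: int = 50    # duration of one spoken syllable, cycles
    cycle_ms: float = 10.0       # real-time duration of one cycle

    # Implementation-level settings (exposed, see docs/methods.md).
    refresh_dwell: int = 2       # cycles of one refresh act
    refresh_switch: int = 1      # extra cycle to move to the next trace
    recreate_mean: float = 8.0   # mean cycles to revive a discarded instance
    recreate_sd: float = 2.0
    prune_floor: float = 0.10    # discarded traces below this are dropped
    discard_decay: float = 0.99  # passive decay of inhibited (OFF) traces
    theta_low: float = 0.40
    theta_high: float = 0.60
    theta_step_down: float = 0.01   # after `theta_k` consecutive corrects
    theta_step_up: float = 0.02     # after an error
    theta_k: int = 5
    access_retry: int = 4        # cycles between retrieval access attempts
    max_item_failures: int = 3   # access failures before an item is skipped
    new_rule_strength: float = 0.05
    new_rule_duration: int = 5


#: (low, standard, high) bounds for the six per-subject sampled parameters.
SAMPLED_RANGES = {
    "alpha": (0.005, 0.02, 0.035),
    "beta": (0.985, 0.99, 0.995),
    "phi": (0.20, 0.25, 0.30),
    "tau": (0.65, 0.75, 0.85),
    "theta": (0.40, 0.50, 0.60),
    "zeta": (0.010, 0.015, 0.020),
}


@dataclass
class SubjectSpec:
    """One statistical subject: id, seed and its six sampled parameter values."""

    subject_id: int
    seed: int
    values: dict = field(default_factory=dict)

    def apply(self, base: ModelParameters) -> ModelParameters:
        return replace(base, **self.values)


def sample_parameter(rng: Random, low: float, mean: float, high: float) -> float:
    """Draw v = r (h - l) / 6 + m, r ~ N(0,1), clipped to [l, h]."""
    v = rng.gauss(0.0, 1.0) * (high - low) / 6.0 + mean
    return min(high, max(low, v))


def sample_subject(subject_id: int, seed: int,
                   base: ModelParameters | None = None) -> SubjectSpec:
    """Sample the six varied parameters for one statistical subject.

    Each parameter uses an independent standard-gaussian draw from the
    subject's own stream, so subjects are reproducible from their seed alone.
    """
    base = base or ModelParameters()
    rng = Random(seed)
    values = {}
    for name, (low, mean_default, high) in SAMPLED_RANGES.items():
        mean = getattr(base, name, mean_default)
        values[name] = sample_parameter(rng, low, mean, high)
    return SubjectSpec(subject_id=subject_id, seed=seed, values=values)


def grow(a: float, rate: float) -> float:
    """Saturating activation growth a + (1 - a) * rate, clipped to [0, 1]."""
    return min(1.0, a + (1.0 - a) * rate)


def decay(a: float, rate: float) -> float:
    """Multiplicative activation decay a * rate."""
    return a * rate


def gauss_duration(rng: Random, mean: float, sd: float, floor: int = 1) -> int:
    """Gaussian duration rounded to the nearest integer cycle, floored."""
    d = round(mean + sd * rng.gauss(0.0, 1.0))
    return max(floor, int(d))


def rehearsal_duration(rng: Random, syllables: int, t_s: int = 50) -> int:
    """One rehearsal act: d = round(0.9 sqrt(n) t_s + r)."""
    d = round(0.9 * math.sqrt(max(1, syllables)) * t_s + rng.gauss(0.0, 1.0))
    return max(1, int(d))


def revival_duration(rng: Random) -> int:
    """One revival act: d = round(25 + r)."""
    return max(1, int(round(25 + rng.gauss(0.0, 1.0))))
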