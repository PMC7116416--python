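"""PGSE sequence timing: maximum b-value → minimum echo time → T2 penalty.

The highest shell dictates the echo time of the whole (constant-TE)
acquisition and hence its SNR.  We model a standard pulsed-gradient
spin-echo sequence with square diffusion gradients of duration δ packed
tightly around the refocusing window, so that the gradient separation is
Δ = δ + t_refocus and

    TE = t_pre + 2δ + t_refocus + t_post,
    b  = γ² G² δ² (Δ − δ/3).

Given a target b_max the pulse duration δ is found by monotone
root-finding, and the resulting signal loss exp(−TE/T2) is applied as a
uniform attenuation of the basis effect sizes — inherently penalising
candidate protocols that demand a high maximum b-value.

The model keeps the four lumped timing constants (pre-gradient delay,
refocusing window, post-gradient delay, gradient strength) and nothing
else: no slew-rate limits, no explicit spin-echo symmetry constraint, no
EPI readout.  Reported echo times are therefore model-dependent lower
bounds, not vendor-exact numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TimingModel",
    "min_echo_time",
    "pulse_duration",
    "b_from_delta",
    "attenuation",
    "attenuated_effect_sizes",
]

#: Proton gyromagnetic ratio, rad s⁻¹ T⁻¹.
GAMMA_PROTON = 2.6752219e8

#: Typical neonatal-brain T2 presets at 3 T, ms (inf = ignore relaxation).
T2_PRESETS_MS = (100.0, 150.0, 200.0, math.inf)


@dataclass(frozen=True)
class TimingModel:
    """Lumped PGSE timing constants.

    All durations in ms; gradient strength in mT/m; t2 in ms (``inf``
    disables relaxation).
    """

    t_pre: float = 5.0        # 90° pulse → first gradient onset
    t_refocus: float = 5.0    # 180° refocusing window incl. crushers
    t_post: float = 15.0      # second gradient end → echo
    gradient_strength: float = 80.0
    gamma: float = GAMMA_PROTON
    t2: float = math.inf

    def __post_init__(self):
        if min(self.t_pre, self.t_refocus, self.t_post) < 0:
            raise ValueError("timing delays must be non-negative")
        if self.gradient_strength <= 0:
            raise ValueError("gradient strength must be positive")
        if not self.t2 > 0:
            raise ValueError("t2 must be positive (inf allowed)")


def b_from_delta(delta_ms: float, model: TimingModel) -> float:
    """b-value (s/mm²) produced by square gradients of duration δ (ms)."""
    delta = np.asarray(delta_ms, dtype=float) * 1e-3  # s
    Delta = delta + model.t_refocus * 1e-3
    g = model.gradient_strength * 1e-3  # T/m
    b_si = (model.gamma * g) ** 2 * delta**2 * (Delta - delta / 3.0)  # s/m²
    return b_si * 1e-6  # s/mm²


def pulse_duration(b_max: float, model: TimingModel) -> float:
    """Gradient pulse duration δ (ms) needed to reach `b_max` (s/mm²).

    b(δ) is strictly increasing, so the root is bracketed and solved to
    1e-6 ms.
    """
    if b_max < 0:
        raise ValueError("b_max must be non-negative")
    if b_max == 0:
        return 0.0
    hi = 1.0
    while b_from_delta(hi, model) < b_max:
        hi *= 2.0
        if hi > 1e5:  # pragma: no cover - unreachable for sane inputs
            raise ValueError("b_max out of reach for this gradient strength")
    return float(brentq(lambda d: b_from_delta(d, model) - b_max,
                        0.0, hi, xtol=1e-6))


def min_echo_time(b_max: float, model: TimingModel | None = None) -> float:
    """Minimum achievable echo time (ms) for a protocol with `b_max` (s/mm²).

    TE = t_pre + 2δ + t_refocus + t_post; at b_max = 0 this reduces to the
    fixed overhead (25 ms with the default constants).
    """
    model = model or TimingModel()
    delta = pulse_duration(b_max, model)
    return model.t_pre + 2.0 * delta + model.t_refocus + model.t_post


def attenuation(te_ms: float, t2_ms: float) -> float:
    """T2 signal attenuation exp(−TE/T2); T2 = inf → 1 (no relaxation)."""
    if te_ms < 0:
        raise ValueError("TE must be non-negative")
    if not t2_ms > 0:
        raise ValueError("t2 must be positive (inf allowed)")
    if math.isinf(t2_ms):
        return 1.0
    return float(math.exp(-te_ms / t2_ms))


def attenuated_effect_sizes(eps, b_max: float,
                            model: TimingModel | None = None) -> np.ndarray:
    """Scale all effect sizes by the T2 attenuation implied by `b_max`.

    The attenuation is uniform across components: a longer echo time costs
    every coefficient the same fraction of signal.
    """
    model = model or TimingModel()
    factor = attenuation(min_echo_time(b_max, model), model.t2)
    return np.asarray(eps, dtype=float) * factor
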