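"""Gene-inactivation dating from mixed-branch dN/dS estimates.

A *transitional* branch spans the interval [T_lower, T_upper] MYA and is a
mixture of a functional portion (duration t_f, ratio omega_f) followed by a
pseudogenic portion (duration t_p, ratio omega_p).  Its estimated ratio
omega_t is the synonymous-substitution-weighted average of the two regimes:

    omega_t = (w_f * omega_f + w_p * omega_p) / (w_f + w_p),

with weights w = synonymous substitutions accumulated on each portion.

One-rate equation (one synonymous rate):  w is proportional to duration, so

    t_p = T * (omega_t - omega_f) / (omega_p - omega_f),      T = T_upper - T_lower.

Two-rate equation (separate functional and pseudogenic synonymous rates
s_f, s_p per MY):  w_f = s_f * t_f and w_p = s_p * t_p, giving

    t_p = s_f * T * (omega_t - omega_f)
          / [ s_p * (omega_p - omega_t) + s_f * (omega_t - omega_f) ].

Because inactivation persists, the pseudogenic portion abuts the descendant
node, so the inactivation date is T_i = T_lower + t_p.  Estimates are
averaged over the eight combinations of codon frequency model (CF1/CF2),
estimated versus fixed (1.0) pseudogenic omega, and one- versus two-rate
equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .models import StructuralError


@dataclass
class DatingInputs:
    T_upper: float  # MYA, ancestral node of the transitional branch
    T_lower: float  # MYA, descendant node
    omega_f: float  # background (functional) ratio
    omega_t: float  # transitional-branch ratio
    omega_p: float  # pseudogenic ratio (estimated or fixed 1.0)
    equation: str = "one_rate"
    s_f: Optional[float] = None  # synonymous subs/site/MY, functional
    s_p: Optional[float] = None  # synonymous subs/site/MY, pseudogenic

    def __post_init__(self) -> None:
        if not self.T_upper > self.T_lower >= 0:
            raise StructuralError(
                f"need T_upper > T_lower >= 0, got {self.T_upper}, {self.T_lower}"
            )
        if min(self.omega_f, self.omega_t, self.omega_p) < 0:
            raise StructuralError("omegas must be non-negative")
        if self.equation not in ("one_rate", "two_rate"):
            raise StructuralError(f"unknown equation {self.equation!r}")
        if self.equation == "two_rate":
            if self.s_f is None or self.s_p is None or self.s_f <= 0 or self.s_p <= 0:
                raise StructuralError("two_rate equation needs s_f, s_p > 0")

    @property
    def duration(self) -> float:
        return self.T_upper - self.T_lower


def solve_mixed_branch(inputs: DatingInputs) -> tuple[float, bool]:
    """Duration t_p of the pseudogenic portion of the transitional branch.

    Returns ``(t_p, clamped)``; t_p is clamped to [0, T] with a diagnostic
    flag when omega_t falls outside [omega_f, omega_p] (noisy estimates can
    exceed the neutral ratio).
    """
    if inputs.omega_p <= inputs.omega_f:
        raise StructuralError(
            f"unidentifiable mixture: omega_p ({inputs.omega_p:.4g}) must "
            f"exceed omega_f ({inputs.omega_f:.4g})"
        )
    T = inputs.duration
    if inputs.omega_t <= inputs.omega_f:
        return 0.0, inputs.omega_t < inputs.omega_f
    if inputs.omega_t >= inputs.omega_p:
        return T, inputs.omega_t > inputs.omega_p
    rise = inputs.omega_t - inputs.omega_f
    if inputs.equation == "one_rate":
        t_p = T * rise / (inputs.omega_p - inputs.omega_f)
    else:
        fall = inputs.omega_p - inputs.omega_t
        t_p = inputs.s_f * T * rise / (inputs.s_p * fall + inputs.s_f * rise)
    return min(max(t_p, 0.0), T), False


def date_inactivation(t_p: float, inputs: DatingInputs) -> float:
    """Calendar date of inactivation onset: the pseudogenic portion abuts
    the descendant node, so T_i = T_lower + t_p."""
    if not 0.0 <= t_p <= inputs.duration + 1e-9:
        raise StructuralError(f"t_p {t_p} outside [0, {inputs.duration}]")
    return inputs.T_lower + min(t_p, inputs.duration)


@dataclass
class ComboEstimate:
    freq_model: str        # CF1 | CF2
    omega_p_mode: str      # estimated | fixed
    equation: str          # one_rate | two_rate
    t_p: float
    T_i: float
    clamped: bool = False
    inputs: Optional[DatingInputs] = None


@dataclass
class InactivationEstimate:
    combos: list[ComboEstimate] = field(default_factory=list)

    @property
    def mean_T_i(self) -> float:
        if not self.combos:
            raise StructuralError("no combination estimates")
        return sum(c.T_i for c in self.combos) / len(self.combos)


EIGHT_COMBINATIONS = tuple(
    (fm, mode, eq)
    for fm in ("CF1", "CF2")
    for mode in ("estimated", "fixed")
    for eq in ("one_rate", "two_rate")
)


def average_combinations(
    per_combo: list[tuple[tuple[str, str, str], DatingInputs]]
) -> InactivationEstimate:
    """Average T_i over the 2 x 2 x 2 grid of analysis combinations.

    ``per_combo`` pairs each (freq_model, omega_p_mode, equation) key with
    its dating inputs; exactly the eight-combination grid is required.
    """
    keys = [k for k, _ in per_combo]
    if sorted(keys) != sorted(EIGHT_COMBINATIONS):
        raise StructuralError(
            "expected exactly the eight {CF1,CF2} x {estimated,fixed} x "
            "{one_rate,two_rate} combinations"
        )
    est = InactivationEstimate()
    for (fm, mode, eq), inputs in per_combo:
        t_p, clamped = solve_mixed_branch(inputs)
        est.combos.append(
            ComboEstimate(freq_model=fm, omega_p_mode=mode, equation=eq,
                          t_p=t_p, T_i=date_inactivation(t_p, inputs),
                          clamped=clamped, inputs=inputs)
        )
    return est


def estimate_terminal_split(
    T_ref: float, mean_terminal_bl: float, mean_path_bl: float
) -> float:
    """Clock-proportional date for the split between two conspecific
    individuals: T_split = T_ref * terminal / path, where the branch
    lengths are in substitutions/site on the same tree."""
    if mean_path_bl <= 0:
        raise StructuralError("mean path branch length must be positive")
    if not 0 <= mean_terminal_bl <= mean_path_bl:
        raise StructuralError(
            "terminal branch length must lie in [0, mean_path_bl]"
        )
    return T_ref * mean_terminal_bl / mean_path_bl
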