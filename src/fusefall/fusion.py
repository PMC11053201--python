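"""Decision-level fusion of the video and audio fall probabilities.

Two combiners are provided.  Linear weighting forms c = α·a + (1−α)·b with α
the video weight (the recommended operating range is α ∈ [0.6, 0.9]: video is
the primary modality, audio the auxiliary one).  Dempster–Shafer evidence
combination works on basic probability assignments (mass functions) over the
frame of discernment Θ = {fall, not-fall}: each modality's probability is
turned into a mass function (optionally discounted toward ignorance by moving
mass to Θ), the two are combined by Dempster's rule with conflict
renormalization 1/(1−K), K = Σ_{B∩C=∅} m1(B)·m2(C), and the decision is taken
on the pignistic probability m({fall}) + m(Θ)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .skeleton import FALL, NOT_FALL

__all__ = [
    "MassFunction",
    "FusedDecision",
    "linear_fuse",
    "mass_from_probability",
    "dempster_combine",
    "belief_plausibility",
    "pignistic",
    "decide",
]

#: Hypothesis sets of the power set of Θ = {fall, not-fall}.
EMPTY = frozenset()
H_FALL = frozenset({FALL})
H_NOT_FALL = frozenset({NOT_FALL})
THETA = frozenset({FALL, NOT_FALL})
HYPOTHESES = (EMPTY, H_FALL, H_NOT_FALL, THETA)

ALPHA_RANGE = (0.6, 0.9)


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over {∅, {fall}, {not-fall}, Θ}."""

    fall: float
    not_fall: float
    theta: float = 0.0
    empty: float = 0.0

    def __post_init__(self):
        vals = (self.fall, self.not_fall, self.theta, self.empty)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ValueError(f"mass values must lie in [0, 1]: {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"mass values must sum to 1, got {sum(vals)}")

    def __getitem__(self, hypothesis: frozenset) -> float:
        return {
            EMPTY: self.empty,
            H_FALL: self.fall,
            H_NOT_FALL: self.not_fall,
            THETA: self.theta,
        }[frozenset(hypothesis)]

    def as_dict(self) -> dict:
        return {EMPTY: self.empty, H_FALL: self.fall,
                H_NOT_FALL: self.not_fall, THETA: self.theta}


VACUOUS = MassFunction(fall=0.0, not_fall=0.0, theta=1.0)


@dataclass
class FusedDecision:
    clip_id: str
    method: str                 # "linear" or "dempster"
    score: float                # fused fall probability (pignistic for D-S)
    label: str
    alpha: float | None = None
    conflict: float | None = None
    mass: MassFunction | None = None


def linear_fuse(a: float, b: float, alpha: float) -> float:
    """c = α·a + (1−α)·b with a the video and b the audio fall probability."""
    a, b, alpha = float(a), float(b), float(alpha)
    for name, v in (("a", a), ("b", b), ("alpha", alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    if not ALPHA_RANGE[0] <= alpha <= ALPHA_RANGE[1]:
        warnings.warn(
            f"alpha={alpha} outside the recommended video-weight range "
            f"{ALPHA_RANGE}",
            stacklevel=2,
        )
    return alpha * a + (1.0 - alpha) * b


def mass_from_probability(p_fall: float, discount: float = 0.0) -> MassFunction:
    """Turn a classifier fall probability into a mass function.

    A ``discount`` fraction of the unit mass is assigned to Θ (ignorance);
    the rest splits between the singletons proportionally to p.  With
    discount 0 this is an ordinary Bayesian assignment.
    """
    p_fall = float(p_fall)
    discount = float(discount)
    if not 0.0 <= p_fall <= 1.0:
        raise ValueError(f"probability {p_fall} outside [0, 1]")
    if not 0.0 <= discount <= 1.0:
        raise ValueError(f"discount {discount} outside [0, 1]")
    return MassFunction(
        fall=(1.0 - discount) * p_fall,
        not_fall=(1.0 - discount) * (1.0 - p_fall),
        theta=discount,
    )


def dempster_combine(m1: MassFunction, m2: MassFunction):
    """Dempster's rule: (m1 ⊕ m2, K) with conflict K = Σ_{B∩C=∅} m1(B)m2(C)."""
    d1, d2 = m1.as_dict(), m2.as_dict()
    conflict = 0.0
    combined = {h: 0.0 for h in HYPOTHESES}
    for b, mb in d1.items():
        for c, mc in d2.items():
            inter = b & c
            if inter:
                combined[inter] += mb * mc
            else:
                conflict += mb * mc
    if conflict >= 1.0 - 1e-12:
        raise ValueError(
            "total conflict (K = 1): the two mass functions are contradictory "
            "certainties and cannot be combined"
        )
    # renormalize by the surviving mass itself (equal to 1-K up to rounding)
    # so the result satisfies the unit-sum contract exactly
    z = combined[H_FALL] + combined[H_NOT_FALL] + combined[THETA]
    return (
        MassFunction(
            fall=combined[H_FALL] / z,
            not_fall=combined[H_NOT_FALL] / z,
            theta=combined[THETA] / z,
        ),
        conflict,
    )


def belief_plausibility(m: MassFunction, hypothesis) -> tuple[float, float]:
    """(bel, pl) for a hypothesis A ⊆ Θ.

    bel(A) sums masses of subsets of A; pl(A) sums masses of sets meeting A;
    [bel, pl] is the credibility interval and pl(A) = 1 − bel(Θ \\ A).
    """
    a = frozenset(hypothesis)
    if not a <= THETA:
        raise ValueError(f"hypothesis {set(hypothesis)} is not a subset of Θ")
    bel = sum(mv for h, mv in m.as_dict().items() if h and h <= a)
    pl = sum(mv for h, mv in m.as_dict().items() if h & a)
    return float(bel), float(pl)


def pignistic(m: MassFunction) -> float:
    """Point fall probability: mass on Θ splits equally between singletons."""
    return m.fall + m.theta / 2.0


def decide(score, threshold: float = 0.5, rule: str = "probability") -> str:
    """Threshold a fused score or mass function; ties go to not-fall.

    Rules: "probability" (plain threshold on a scalar), "pignistic"
    (threshold m({fall}) + m(Θ)/2), "belief" (threshold bel({fall})).
    """
    if isinstance(score, MassFunction):
        if rule == "belief":
            value = belief_plausibility(score, H_FALL)[0]
        else:
            value = pignistic(score)
    else:
        value = float(score)
    return FALL if value > threshold else NOT_FALL


def fuse_linear_decision(
    clip_id: str, a: float, b: float, alpha: float = 0.7,
    threshold: float = 0.5,
) -> FusedDecision:
    c = linear_fuse(a, b, alpha)
    return FusedDecision(
        clip_id=clip_id, method="linear", score=c,
        label=decide(c, threshold), alpha=alpha,
    )


def fuse_dempster_decision(
    clip_id: str, a: float, b: float, discount: float = 0.0,
    threshold: float = 0.5, rule: str = "pignistic",
) -> FusedDecision:
    m, conflict = dempster_combine(
        mass_from_probability(a, discount), mass_from_probability(b, discount)
    )
    score = pignistic(m)
    return FusedDecision(
        clip_id=clip_id, method="dempster", score=score,
        label=decide(m, threshold, rule), conflict=conflict, mass=m,
    )
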