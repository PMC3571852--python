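"""Fuzzy Bayesian network fusion of the five drowsiness indicators.

The five parents — heart rate (HR, bpm), blood pressure (BP, mmHg),
temperature (TP, degC), speed (SP, km/h) and PERCLOS (PR, fraction) — each
carry fuzzy states defined by membership functions.  A crisp measurement is
fuzzified to a normalized state distribution; the joint weight of every
combination in the Cartesian product of parent states is the product t-norm
of the chosen per-parent degrees; and the fatigue probability pair is the
CPT-weighted sum over all combinations:

    p_true  = sum_p t_norm_p * cpt_p
    p_false = sum_p t_norm_p * (1 - cpt_p)

Because normalized memberships make the t-norms sum to exactly 1 (a product
of sums), and each CPT row pair sums to 1, p_true + p_false = 1.

The fused p_true drives three layers of interpretation: a soft-binned
safe/warning/dangerous state distribution with max-probability selection, a
banded vigilance label (awake 0.30-0.54, partial-sleep 0.60-0.75, alert
above 0.75, with the unmapped gaps surfaced as below-range/indeterminate),
and a strict alert trigger at p_true > 0.75.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError, OutOfSupportError

__all__ = [
    "MembershipFunction",
    "FuzzyVariable",
    "FuzzyStateVector",
    "CPT",
    "JointMembership",
    "FatigueDistribution",
    "VigilanceAssessment",
    "AlertDecision",
    "FusionNetwork",
    "fuzzify",
    "joint_memberships",
    "infer_fatigue",
    "state_distribution",
    "classify_vigilance",
    "alert_decision",
    "default_network",
]

log = logging.getLogger(__name__)

PARENT_NAMES = ("HR", "BP", "TP", "SP", "PR")
OUTPUT_STATES = ("safe", "warning", "dangerous")
ALERT_THRESHOLD = 0.75

#: vigilance bands on p_true: (lo, hi, lo_inclusive, hi_inclusive, label)
DEFAULT_INTERVALS = (
    (0.00, 0.30, True, False, "below-range"),
    (0.30, 0.54, True, True, "awake"),
    (0.54, 0.60, False, False, "indeterminate"),
    (0.60, 0.75, True, True, "partial-sleep"),
    (0.75, 1.00, False, True, "alert"),
)

ADVISORIES = {
    "partial-sleep": "rest",
    "alert": "warning-service",
}


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular or trapezoidal membership function.

    ``breakpoints`` are (a, b, c) for a triangle or (a, b, c, d) for a
    trapezoid; ``-inf``/``inf`` shoulders give open-ended low/high states.
    Evaluates to [0, 1].
    """

    label: str
    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self):
        pts = tuple(float(p) for p in self.breakpoints)
        n = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if n is None:
            raise ConfigError(f"unknown membership shape {self.shape!r}")
        if len(pts) != n:
            raise ConfigError(f"{self.shape} needs {n} breakpoints, got {len(pts)}")
        if list(pts) != sorted(pts):
            raise ConfigError("breakpoints must be sorted")
        object.__setattr__(self, "breakpoints", pts)

    def __call__(self, x: float) -> float:
        if self.shape == "triangular":
            a, b, c = self.breakpoints
            lo, hi, plateau_lo, plateau_hi = a, c, b, b
        else:
            a, b, c, d = self.breakpoints
            lo, hi, plateau_lo, plateau_hi = a, d, b, c
        if x < lo or x > hi:
            return 0.0
        if plateau_lo <= x <= plateau_hi:
            return 1.0
        if x < plateau_lo:
            if math.isinf(lo):
                return 1.0
            return (x - lo) / (plateau_lo - lo) if plateau_lo > lo else 1.0
        if math.isinf(hi):
            return 1.0
        return (hi - x) / (hi - plateau_hi) if hi > plateau_hi else 1.0


@dataclass(frozen=True)
class FuzzyVariable:
    """A named indicator with one membership function per linguistic state."""

    name: str
    membership_functions: tuple[MembershipFunction, ...]

    def __post_init__(self):
        mfs = tuple(self.membership_functions)
        if len(mfs) < 2:
            raise ConfigError(f"variable {self.name} needs >= 2 states")
        labels = [m.label for m in mfs]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate state labels in variable {self.name}")
        object.__setattr__(self, "membership_functions", mfs)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(m.label for m in self.membership_functions)


@dataclass(frozen=True)
class FuzzyStateVector:
    """Normalized membership degrees of one variable (they sum to 1)."""

    variable: str
    states: tuple[str, ...]
    degrees: tuple[float, ...]

    def __post_init__(self):
        d = tuple(float(x) for x in self.degrees)
        if len(d) != len(self.states):
            raise ConfigError("one degree per state required")
        if any(x < -1e-12 or x > 1 + 1e-12 for x in d):
            raise ConfigError("degrees must lie in [0, 1]")
        if abs(sum(d) - 1.0) > 1e-9:
            raise ConfigError("degrees must be normalized to sum 1")
        object.__setattr__(self, "degrees", d)


def fuzzify(value: float, variable: FuzzyVariable) -> FuzzyStateVector:
    """Evaluate every membership function at ``value`` and normalize.

    Raises OutOfSupportError when the value activates no state at all;
    callers then hold the last valid state vector.
    """
    raw = [mf(value) for mf in variable.membership_functions]
    total = sum(raw)
    if total <= 0:
        raise OutOfSupportError(
            f"value {value!r} outside the support of every state of {variable.name}"
        )
    return FuzzyStateVector(
        variable=variable.name,
        states=variable.states,
        degrees=tuple(r / total for r in raw),
    )


@dataclass(frozen=True)
class JointMembership:
    """One joint parent-state combination and its product t-norm weight."""

    combination: tuple[str, ...]
    t_norm: float


@dataclass
class CPT:
    """Conditional probability table over the Cartesian parent-state product.

    ``entries`` maps each joint combination (a tuple of state labels, one
    per parent in ``parent_order``) to P(fatigue=true | combination); the
    false column is the complement, so every row pair sums to 1.
    """

    parent_order: tuple[str, ...]
    parent_states: dict[str, tuple[str, ...]]
    entries: dict[tuple[str, ...], float]

    def __post_init__(self):
        combos = list(itertools.product(*(self.parent_states[p] for p in self.parent_order)))
        if set(self.entries) != set(combos):
            missing = sorted(set(combos) - set(self.entries))[:5]
            extra = sorted(set(self.entries) - set(combos))[:5]
            raise ConfigError(
                f"CPT must cover every combination exactly once; "
                f"missing={missing} unexpected={extra}"
            )
        for combo, p in self.entries.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"CPT probability {p} for {combo} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.entries)

    def p_true(self, combination: tuple[str, ...]) -> float:
        return self.entries[combination]

    def p_false(self, combination: tuple[str, ...]) -> float:
        return 1.0 - self.entries[combination]

    @classmethod
    def noisy_or(
        cls,
        parent_order: tuple[str, ...],
        parent_states: dict[str, tuple[str, ...]],
        fatigued_state: dict[str, str],
        weights: dict[str, float],
        leak: float,
    ) -> "CPT":
        """Noisy-OR table: monotone non-decreasing in every fatigued parent.

        P(true | combo) = 1 - (1 - leak) * prod over fatigued parents of
        (1 - weight).
        """
        if not (0.0 <= leak < 1.0):
            raise ConfigError("leak must lie in [0, 1)")
        entries = {}
        for combo in itertools.product(*(parent_states[p] for p in parent_order)):
            keep = 1.0 - leak
            for parent, state in zip(parent_order, combo):
                if state == fatigued_state[parent]:
                    keep *= 1.0 - weights[parent]
            entries[combo] = 1.0 - keep
        return cls(parent_order=tuple(parent_order), parent_states=dict(parent_states),
                   entries=entries)


def joint_memberships(vectors: list[FuzzyStateVector], cpt: CPT) -> list[JointMembership]:
    """Product t-norm weight for every combination in the parent product."""
    by_name = {v.variable: v for v in vectors}
    missing = [p for p in cpt.parent_order if p not in by_name]
    if missing:
        raise ConfigError(f"missing parent state vectors: {missing}")
    ordered = [by_name[p] for p in cpt.parent_order]
    for vec, parent in zip(ordered, cpt.parent_order):
        if tuple(vec.states) != tuple(cpt.parent_states[parent]):
            raise ConfigError(
                f"state mismatch for {parent}: vector {vec.states} vs "
                f"CPT {cpt.parent_states[parent]}"
            )
    out = []
    for combo in itertools.product(*(range(len(v.states)) for v in ordered)):
        t = 1.0
        labels = []
        for vec, idx in zip(ordered, combo):
            t *= vec.degrees[idx]
            labels.append(vec.states[idx])
        out.append(JointMembership(combination=tuple(labels), t_norm=t))
    return out


@dataclass(frozen=True)
class FatigueDistribution:
    p_false: float
    p_true: float
    state_probs: dict[str, float]
    selected_state: str

    @property
    def vigilance_index(self) -> float:
        """Fused probability on the 0-100 display scale."""
        return 100.0 * self.p_true


def state_distribution(p_true: float) -> dict[str, float]:
    """Soft-bin p_true into safe/warning/dangerous probabilities.

    Bin membership ramps span the band boundaries (0.54-0.60 between safe
    and warning, 0.75-0.80 between warning and dangerous), then normalize.
    """
    safe = MembershipFunction("safe", "trapezoidal", (-math.inf, -math.inf, 0.54, 0.60))
    warning = MembershipFunction("warning", "trapezoidal", (0.54, 0.60, 0.75, 0.80))
    dangerous = MembershipFunction("dangerous", "trapezoidal", (0.75, 0.80, math.inf, math.inf))
    raw = {m.label: m(p_true) for m in (safe, warning, dangerous)}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def infer_fatigue(joints: list[JointMembership], cpt: CPT) -> FatigueDistribution:
    """CPT-weighted sum over the joint combinations.

    The false branch reuses the same joint weights with the CPT's
    complement column, so p_false + p_true = 1 whenever every row pair sums
    to 1 and the inputs are normalized.
    """
    seen = {j.combination for j in joints}
    expected = set(cpt.entries)
    if seen != expected:
        missing = sorted(expected - seen)[:5]
        raise ConfigError(f"joint memberships do not cover the CPT; missing={missing}")
    p_true = sum(j.t_norm * cpt.p_true(j.combination) for j in joints)
    p_false = sum(j.t_norm * cpt.p_false(j.combination) for j in joints)
    probs = state_distribution(p_true)
    selected = max(probs, key=probs.get)
    return FatigueDistribution(
        p_false=p_false, p_true=p_true, state_probs=probs, selected_state=selected
    )


@dataclass(frozen=True)
class VigilanceAssessment:
    selected_state: str
    interval_label: str
    advisory: str | None
    p_true: float


def classify_vigilance(
    dist: FatigueDistribution, intervals=DEFAULT_INTERVALS
) -> VigilanceAssessment:
    """Max-probability output state plus the banded vigilance label."""
    label = "indeterminate"
    for lo, hi, lo_inc, hi_inc, name in intervals:
        above = dist.p_true > lo or (lo_inc and dist.p_true == lo)
        below = dist.p_true < hi or (hi_inc and dist.p_true == hi)
        if above and below:
            label = name
            break
    if label == "indeterminate":
        log.info("p_true %.3f falls in an unmapped vigilance band", dist.p_true)
    return VigilanceAssessment(
        selected_state=dist.selected_state,
        interval_label=label,
        advisory=ADVISORIES.get(label),
        p_true=dist.p_true,
    )


@dataclass(frozen=True)
class AlertDecision:
    triggered: bool
    trigger_probability: float
    threshold: float = ALERT_THRESHOLD


def alert_decision(dist: FatigueDistribution, threshold: float = ALERT_THRESHOLD) -> AlertDecision:
    """Trigger strictly above the threshold (p_true > threshold)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigError("alert threshold must lie in (0, 1)")
    return AlertDecision(
        triggered=dist.p_true > threshold,
        trigger_probability=dist.p_true,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# network container + config


@dataclass
class FusionNetwork:
    """The five fuzzified parents plus their CPT, with one-call inference."""

    variables: dict[str, FuzzyVariable]
    cpt: CPT
    alert_threshold: float = ALERT_THRESHOLD
    intervals: tuple = DEFAULT_INTERVALS

    def __post_init__(self):
        for p in self.cpt.parent_order:
            if p not in self.variables:
                raise ConfigError(f"CPT parent {p} has no variable definition")

    def fuzzify_all(self, values: dict[str, float]) -> list[FuzzyStateVector]:
        return [fuzzify(values[p], self.variables[p]) for p in self.cpt.parent_order]

    def infer(self, vectors: list[FuzzyStateVector]) -> FatigueDistribution:
        return infer_fatigue(joint_memberships(vectors, self.cpt), self.cpt)

    def assess(self, values: dict[str, float]):
        """values -> (FatigueDistribution, VigilanceAssessment, AlertDecision)."""
        dist = self.infer(self.fuzzify_all(values))
        return dist, classify_vigilance(dist, self.intervals), alert_decision(
            dist, self.alert_threshold
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alert_threshold": self.alert_threshold,
            "variables": {
                name: [
                    {"label": m.label, "shape": m.shape,
                     "breakpoints": [_num_out(p) for p in m.breakpoints]}
                    for m in var.membership_functions
                ]
                for name, var in self.variables.items()
            },
            "cpt": {
                "parent_order": list(self.cpt.parent_order),
                "parent_states": {k: list(v) for k, v in self.cpt.parent_states.items()},
                "entries": [
                    {"combination": list(c), "p_true": p}
                    for c, p in sorted(self.cpt.entries.items())
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionNetwork":
        variables = {
            name: FuzzyVariable(
                name=name,
                membership_functions=tuple(
                    MembershipFunction(
                        label=m["label"], shape=m["shape"],
                        breakpoints=tuple(_num_in(p) for p in m["breakpoints"]),
                    )
                    for m in mfs
                ),
            )
            for name, mfs in d["variables"].items()
        }
        c = d["cpt"]
        cpt = CPT(
            parent_order=tuple(c["parent_order"]),
            parent_states={k: tuple(v) for k, v in c["parent_states"].items()},
            entries={tuple(e["combination"]): float(e["p_true"]) for e in c["entries"]},
        )
        return cls(variables=variables, cpt=cpt,
                   alert_threshold=float(d.get("alert_threshold", ALERT_THRESHOLD)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FusionNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _num_out(x: float):
    if math.isinf(x):
        return ".inf" if x > 0 else "-.inf"
    return float(x)


def _num_in(x) -> float:
    if isinstance(x, str):
        return float(x.replace(".inf", "inf"))
    return float(x)


def default_network() -> FusionNetwork:
    """Binary-state defaults for the five indicators plus a noisy-OR CPT.

    Breakpoints mark where each indicator starts to look drowsy: a PERCLOS
    ramp from 0.15 to 0.40, below-resting heart rate (65 down to 55 bpm),
    low pulse pressure surrogate (95 down to 85 mmHg), a warm cabin (24 up
    to 28 degC) and sustained high speed (60 up to 80 km/h).  These carry
    no external authority; they are package defaults, fully configurable,
    and the synthetic generator is parameterized to match them.
    """
    inf = math.inf

    def low(name, a, b):  # fatigued when low
        return (
            MembershipFunction("fatigued", "trapezoidal", (-inf, -inf, a, b)),
            MembershipFunction("normal", "trapezoidal", (a, b, inf, inf)),
        )

    def high(name, a, b):  # fatigued when high
        return (
            MembershipFunction("normal", "trapezoidal", (-inf, -inf, a, b)),
            MembershipFunction("fatigued", "trapezoidal", (a, b, inf, inf)),
        )

    variables = {
        "HR": FuzzyVariable("HR", low("HR", 55.0, 65.0)),
        "BP": FuzzyVariable("BP", low("BP", 85.0, 95.0)),
        "TP": FuzzyVariable("TP", high("TP", 24.0, 28.0)),
        "SP": FuzzyVariable("SP", high("SP", 60.0, 80.0)),
        "PR": FuzzyVariable("PR", high("PR", 0.15, 0.40)),
    }
    states = {name: variables[name].states for name in PARENT_NAMES}
    cpt = CPT.noisy_or(
        parent_order=PARENT_NAMES,
        parent_states=states,
        fatigued_state={p: "fatigued" for p in PARENT_NAMES},
        weights={"HR": 0.55, "BP": 0.45, "TP": 0.25, "SP": 0.25, "PR": 0.85},
        leak=0.32,
    )
    return FusionNetwork(variables=variables, cpt=cpt)
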