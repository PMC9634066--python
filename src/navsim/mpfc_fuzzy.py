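"""mPFC retrieval controller: a fuzzy lookup-table over (here, goal, attention).

Rules have the form

    IF here is A_here AND goal is A_goal AND attention is A_att
    THEN next-step is Ybar

with Gaussian membership functions (sigma = 0.15) centred on the landmark-id
axis for `here`, `goal` and the consequent, and saturating S/Z membership
functions (foot = 1, shoulder = 2) for the attention level, whose crossover
at 1.5 is the attention-deficit threshold.  Inference uses the product
engine with centre-average defuzzification:

    Y = sum_i Ybar_i * prod_j mu_ij(x_j)  /  sum_i prod_j mu_ij(x_j)

so the crisp output is a convex combination of the firing rules' consequent
centres; for routing it is additionally snapped to the nearest firing
consequent centre.

For the six-landmark default map the complete base covers 6 x 6 (here, goal)
combinations x 2 attention states = 72 rules; the two learned routes
(LM1->LM6 and LM4->LM1) activate 10 + 6 = 16 of them.  With attention the
consequent is the next landmark along the route toward the goal; without
attention it is the wrong-path branch attached at the current landmark.

The controller receives landmark *frequency codes* from perception; they are
converted to the id axis through the cognitive map's affine code<->id
relation before membership evaluation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .cogmap import CognitiveMap

__all__ = [
    "MembershipFunction",
    "FuzzyRule",
    "FuzzyRuleBase",
    "InferenceResult",
    "evaluate_mf",
    "build_complete_rulebase",
    "active_rules",
    "infer_next_step",
    "prune_by_degree",
    "write_rules_csv",
    "read_rules_csv",
]

log = logging.getLogger(__name__)

SIGMA_DEFAULT = 0.15
ATTENTION_FOOT = 1.0
ATTENTION_SHOULDER = 2.0
#: smf/zmf crossover: below this the low-attention rules dominate.
ATTENTION_THRESHOLD = 1.5

WITH_ATTENTION = "with"
WITHOUT_ATTENTION = "without"


@dataclass(frozen=True)
class MembershipFunction:
    """Gaussian, S-shaped or Z-shaped membership function on one input axis."""

    shape: str                      # "gaussian" | "s_shape" | "z_shape"
    center: float = 0.0             # gaussian
    sigma: float = SIGMA_DEFAULT    # gaussian
    foot: float = ATTENTION_FOOT    # s/z
    shoulder: float = ATTENTION_SHOULDER

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "s_shape", "z_shape"):
            raise ValueError(f"unknown membership shape {self.shape!r}")
        if self.shape == "gaussian" and self.sigma <= 0:
            raise ValueError(f"gaussian sigma must be positive, got {self.sigma}")
        if self.shape != "gaussian" and not self.foot < self.shoulder:
            raise ValueError("s/z shapes need foot < shoulder")

    def __call__(self, x: float) -> float:
        return evaluate_mf(self, x)


def _smf(x, a, b):
    """Quadratic-spline S-function: 0 at/below a, 1 at/above b."""
    x = np.asarray(x, dtype=float)
    m = (a + b) / 2.0
    out = np.where(
        x <= a,
        0.0,
        np.where(
            x <= m,
            2 * ((x - a) / (b - a)) ** 2,
            np.where(x <= b, 1 - 2 * ((x - b) / (b - a)) ** 2, 1.0),
        ),
    )
    return out


def evaluate_mf(mf: MembershipFunction, x: float):
    """Membership value(s) in [0, 1]; gaussian uses exp(-(x-c)^2 / (2 sigma^2))."""
    if mf.shape == "gaussian":
        if mf.sigma <= 0:
            raise ValueError("gaussian sigma must be positive")
        z = (np.asarray(x, dtype=float) - mf.center) / mf.sigma
        return np.exp(-0.5 * z * z)
    if mf.shape == "s_shape":
        return _smf(x, mf.foot, mf.shoulder)
    return 1.0 - _smf(x, mf.foot, mf.shoulder)


@dataclass(frozen=True)
class FuzzyRule:
    """One lookup-table rule; centres live on the landmark-id axis."""

    here_center: float
    goal_center: float
    attention_label: str     # "with" | "without"
    consequent_center: float

    def __post_init__(self) -> None:
        if self.attention_label not in (WITH_ATTENTION, WITHOUT_ATTENTION):
            raise ValueError(f"unknown attention label {self.attention_label!r}")


@dataclass
class FuzzyRuleBase:
    """Rule list plus the shared membership-function families."""

    rules: list[FuzzyRule]
    sigma: float = SIGMA_DEFAULT
    attention_foot: float = ATTENTION_FOOT
    attention_shoulder: float = ATTENTION_SHOULDER

    @property
    def R(self) -> int:
        return len(self.rules)

    N: int = field(default=3, init=False)  # input dimensions: here, goal, attention

    def attention_membership(self, label: str, attention: float) -> float:
        shape = "s_shape" if label == WITH_ATTENTION else "z_shape"
        mf = MembershipFunction(
            shape, foot=self.attention_foot, shoulder=self.attention_shoulder
        )
        return float(evaluate_mf(mf, attention))

    def firing_strengths(
        self, here: float, goal: float, attention: float
    ) -> np.ndarray:
        """Product firing strength of every rule at the crisp input point."""
        h = np.array([r.here_center for r in self.rules])
        g = np.array([r.goal_center for r in self.rules])
        mu_h = np.exp(-0.5 * ((here - h) / self.sigma) ** 2)
        mu_g = np.exp(-0.5 * ((goal - g) / self.sigma) ** 2)
        att_with = self.attention_membership(WITH_ATTENTION, attention)
        att_without = self.attention_membership(WITHOUT_ATTENTION, attention)
        mu_a = np.array(
            [
                att_with if r.attention_label == WITH_ATTENTION else att_without
                for r in self.rules
            ]
        )
        return mu_h * mu_g * mu_a

    def audit_completeness(
        self,
        here_range=(3.8, 9.2),
        goal_range=(3.8, 9.2),
        attention_range=(0.5, 2.5),
        n: int = 25,
        on_id_axis: bool = False,
    ) -> bool:
        """True iff at least one rule fires everywhere on a dense input grid.

        Ranges default to the frequency-code span of the six landmarks; set
        ``on_id_axis=True`` to pass id-axis ranges directly.
        """
        if not on_id_axis:
            here_range = tuple((c - 3) for c in here_range)  # default-map affine
            goal_range = tuple((c - 3) for c in goal_range)
        for h in np.linspace(*here_range, n):
            for g in np.linspace(*goal_range, n):
                for a in np.linspace(*attention_range, 5):
                    if self.firing_strengths(h, g, a).sum() <= 0:
                        return False
        return True


@dataclass(frozen=True)
class InferenceResult:
    """Raw defuzzified output plus the discrete routing decision."""

    raw: float           # centre-average output on the id axis
    snapped_id: int      # nearest firing consequent centre
    next_code: float     # frequency code of the snapped landmark (if resolvable)


# ---------------------------------------------------------------------------
# rule-base construction
# ---------------------------------------------------------------------------


def build_complete_rulebase(
    cmap: CognitiveMap,
    overrides: dict[tuple[int, int, str], float] | None = None,
) -> FuzzyRuleBase:
    """One rule per (here, goal) route-landmark pair and attention state.

    Consequents: with attention, the next landmark along the route toward the
    goal (stay when here == goal); without attention, the wrong-path branch
    attached at the current landmark (stay when none is attached).
    ``overrides`` replaces individual consequents, keyed by
    (here_id, goal_id, attention_label).
    """
    route_ids = [lm.id for lm in cmap.route_landmarks()]
    if not route_ids:
        raise ValueError("map has no route landmarks")
    overrides = overrides or {}
    rules: list[FuzzyRule] = []
    for here in route_ids:
        for goal in route_ids:
            toward = here + int(np.sign(goal - here))
            branch = cmap.wrong_branches.get(here, here)
            for label, consequent in (
                (WITH_ATTENTION, toward),
                (WITHOUT_ATTENTION, branch if here != goal else here),
            ):
                consequent = overrides.get((here, goal, label), consequent)
                rules.append(FuzzyRule(float(here), float(goal), label, float(consequent)))
    return FuzzyRuleBase(rules=rules)


def active_rules(base: FuzzyRuleBase, start: int, goal: int) -> list[FuzzyRule]:
    """Rules whose (here, goal) lie on the start->goal route, both attention states.

    On the linear landmark chain the route from start to goal is the id
    interval walked in order; the goal itself issues no further step.
    """
    here_ids = {r.here_center for r in base.rules}
    if float(start) not in here_ids or float(goal) not in here_ids:
        raise ValueError(f"unreachable route {start}->{goal}: landmark not in rule base")
    step = 1 if goal >= start else -1
    on_path = set(range(start, goal, step))
    return [
        r
        for r in base.rules
        if r.goal_center == float(goal) and r.here_center in {float(i) for i in on_path}
    ]


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer_next_step(
    base: FuzzyRuleBase | list[FuzzyRule],
    here: float,
    goal: float,
    attention: float,
    cmap: CognitiveMap | None = None,
    units: str = "id",
) -> InferenceResult:
    """Product-inference / centre-average defuzzification over the firing rules.

    ``here`` and ``goal`` are on the landmark-id axis by default; pass
    ``units="code"`` (with ``cmap``) to supply perceived frequency codes.
    Raises ``ValueError`` if no rule fires (completeness violation).
    """
    if units == "code":
        if cmap is None:
            raise ValueError("units='code' requires the cognitive map")
        here = cmap.code_to_id(here)
        goal = cmap.code_to_id(goal)
    elif units != "id":
        raise ValueError(f"unknown units {units!r}")

    if isinstance(base, FuzzyRuleBase):
        rb = base
    else:
        rb = FuzzyRuleBase(rules=list(base))
    w = rb.firing_strengths(here, goal, attention)
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"no rule fires for (here={here}, goal={goal}, attention={attention}); "
            "rule base incomplete at this point"
        )
    ybar = np.array([r.consequent_center for r in rb.rules])
    raw = float((w * ybar).sum() / total)

    firing = w > 0
    centers = np.unique(ybar[firing])
    snapped = float(centers[np.argmin(np.abs(centers - raw))])
    # exact distance tie -> lower centre (np.argmin already keeps the first =
    # lowest, since centers is sorted ascending)
    next_code = cmap.id_to_code(snapped) if cmap is not None else snapped
    return InferenceResult(raw=raw, snapped_id=int(round(snapped)), next_code=next_code)


def prune_by_degree(
    candidates: list[tuple[FuzzyRule, float]],
) -> list[FuzzyRule]:
    """Keep, per antecedent, the candidate rule with the highest degree.

    ``degree`` is the product of antecedent and consequent membership of the
    rule's generating exemplar.  Exact ties keep the lowest consequent centre
    and log a warning.  Candidates with distinct antecedents pass through
    unchanged (input order preserved).
    """
    best: dict[tuple[float, float, str], tuple[FuzzyRule, float]] = {}
    order: list[tuple[float, float, str]] = []
    for rule, degree in candidates:
        key = (rule.here_center, rule.goal_center, rule.attention_label)
        if key not in best:
            best[key] = (rule, degree)
            order.append(key)
            continue
        kept, kept_deg = best[key]
        if degree > kept_deg:
            best[key] = (rule, degree)
        elif degree == kept_deg and rule.consequent_center != kept.consequent_center:
            winner = min((kept, rule), key=lambda r: r.consequent_center)
            log.warning(
                "degree tie for antecedent %s: keeping lower consequent %s",
                key,
                winner.consequent_center,
            )
            best[key] = (winner, kept_deg)
    return [best[k][0] for k in order]


# ---------------------------------------------------------------------------
# CSV I/O (columns: here, goal, attention_label, next_step)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("here", "goal", "attention_label", "next_step")


def write_rules_csv(path, rules) -> None:
    rules = rules.rules if isinstance(rules, FuzzyRuleBase) else rules
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for r in rules:
            w.writerow(
                [_fmt(r.here_center), _fmt(r.goal_center), r.attention_label,
                 _fmt(r.consequent_center)]
            )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def read_rules_csv(path) -> list[FuzzyRule]:
    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [f for f in _CSV_FIELDS if f not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        for i, row in enumerate(reader):
            try:
                rules.append(
                    FuzzyRule(
                        float(row["here"]),
                        float(row["goal"]),
                        row["attention_label"].strip(),
                        float(row["next_step"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: bad rule on data row {i + 1}: {exc}") from exc
    return rules
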