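"""Closed-loop navigation agent tying perception, retrieval control and movement.

Each decision cycle follows the perception-retrieval loop: the agent stands
at a landmark, the what-stream oscillator bank identifies it (or fails to,
in the Alzheimer's regime), the identity is checked against the expectation
held in the next-subgoal short-term-memory buffer, the fuzzy mPFC controller
retrieves the next step for the current (here, goal, attention) input, the
retrieved memory row is loaded into the next-subgoal buffer (shifting the old
content into the previous-subgoal buffer), and the agent moves to the
retrieved landmark.  The cycle repeats until the goal is reached, the step
budget is exhausted ("lost"), or no outgoing path exists ("stuck").

Attention below the smf/zmf crossover (1.5) makes the low-attention rules
fire, so at a decision landmark the controller emits the attached wrong-path
branch; the agent enters it and stays there until attention recovers, then
backtracks to the decision landmark and reapplies the high-attention rule.

When retrieval fails (lesioned map rows, or no landmark recognised in the
AD regime) the next step is decided by weighted path competition: candidate
neighbours are weighted by closeness of their frequency code to the lost
information, ties falling back to the smallest turning angle from the
previous heading, then the lowest landmark id.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .cogmap import CognitiveMap, CognitiveMapRow, build_default_map, ROLE_WRONG_PATH
from .mpfc_fuzzy import (
    ATTENTION_THRESHOLD,
    FuzzyRuleBase,
    build_complete_rulebase,
    infer_next_step,
)
from .what_stream import bank_response, default_bank, recognize_landmark

__all__ = [
    "AgentState",
    "TraceRecord",
    "NavigationTrace",
    "ScenarioConfig",
    "load_preset",
    "perceive",
    "check_expectation",
    "choose_by_competition",
    "Navigator",
    "run_scenario",
]

log = logging.getLogger(__name__)

PRESETS = ("fig12", "fig13", "ad")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "preset", "start", "goal", "here_code", "goal_code", "attention", "lam",
    "B", "As", "dt", "t_end", "seed", "max_steps", "initial_heading",
    "competition_rng",
}


@dataclass
class ScenarioConfig:
    """Validated description of one closed-loop navigation run."""

    start: int = 1
    goal: int = 6
    here_code: float | None = None          # perceived code at the start (may jitter)
    goal_code: float | None = None
    attention: float | list[float] = 2.3    # constant, or piecewise per decision step
    lam: float = 0.2
    B: float = 1.5
    As: float = 1.0
    dt: float = 0.005
    t_end: float = 80.0
    seed: int | None = None
    max_steps: int | None = None            # default: 4 x route length
    initial_heading: tuple[float, float] = (1.0, 0.0)
    competition_rng: bool = False
    preset: str = "custom"

    def validate(self, cmap: CognitiveMap) -> None:
        errors = []
        if self.start not in cmap.landmarks:
            errors.append(f"start: unknown landmark id {self.start}")
        if self.goal not in cmap.landmarks:
            errors.append(f"goal: unknown landmark id {self.goal}")
        atts = self.attention if isinstance(self.attention, list) else [self.attention]
        if not atts or any(a < 0 for a in atts):
            errors.append(f"attention: must be non-negative, got {self.attention}")
        if self.As < 0:
            errors.append(f"As: must be >= 0, got {self.As}")
        if self.dt <= 0 or self.t_end <= 0:
            errors.append(f"dt/t_end: must be positive, got {self.dt}/{self.t_end}")
        if self.max_steps is not None and self.max_steps < 0:
            errors.append(f"max_steps: must be >= 0, got {self.max_steps}")
        if errors:
            raise ValueError("invalid scenario config: " + "; ".join(errors))

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        unknown = set(doc) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(
                f"unknown scenario config field(s): {', '.join(sorted(unknown))}"
            )
        cfg = cls(**{k: v for k, v in doc.items()})
        if isinstance(cfg.initial_heading, list):
            cfg.initial_heading = tuple(cfg.initial_heading)
        return cfg

    def attention_at(self, step: int) -> float:
        if isinstance(self.attention, list):
            return float(self.attention[min(step, len(self.attention) - 1)])
        return float(self.attention)


def load_preset(name: str) -> ScenarioConfig:
    """Load one of the packaged scenario presets: fig12, fig13, ad."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    text = resources.files("navsim").joinpath(f"presets/{name}.yaml").read_text()
    return ScenarioConfig.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# state and trace
# ---------------------------------------------------------------------------


@dataclass
class AgentState:
    """Instantaneous agent state, including the two STM subgoal buffers."""

    position: tuple[float, float]
    heading: tuple[float, float]
    here_code: float | None = None
    stm_next: CognitiveMapRow | None = None
    stm_prev: CognitiveMapRow | None = None
    attention: float = 2.3
    on_wrong_path: bool = False
    decision_position: tuple[float, float] | None = None


@dataclass
class TraceRecord:
    step: int
    x: float
    y: float
    landmark_id: int | None
    recognized_code: float | None
    attention: float
    raw_output: float | None
    snapped_id: int | None
    wrong_path_message: bool = False
    entered_wrong_branch: bool = False
    corrected: bool = False
    stayed: bool = False
    stuck: bool = False
    stm_next: tuple | None = None
    stm_prev: tuple | None = None


@dataclass
class NavigationTrace:
    """Time-ordered record of a run, plus its outcome."""

    records: list[TraceRecord] = field(default_factory=list)
    outcome: str = "goal"        # "goal" | "lost" | "stuck"

    @property
    def reached_goal(self) -> bool:
        return self.outcome == "goal"

    @property
    def visited(self) -> list[int]:
        """Landmark ids the agent moved to, in order (decision steps only)."""
        return [r.snapped_id for r in self.records if r.snapped_id is not None and not r.stayed]

    @property
    def n_decision_steps(self) -> int:
        return sum(1 for r in self.records if not r.stayed and not r.stuck)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            cols = [f for f in TraceRecord.__dataclass_fields__]
            w.writerow(cols)
            for r in self.records:
                d = asdict(r)
                w.writerow([d[c] for c in cols])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"outcome": self.outcome, "records": [asdict(r) for r in self.records]},
                fh,
                indent=2,
                default=lambda o: list(o) if isinstance(o, tuple) else o,
            )

    def summary(self) -> str:
        lines = [
            f"outcome: {self.outcome}",
            f"decision steps: {self.n_decision_steps}",
            f"visited landmarks: {self.visited}",
            f"wrong-path excursions: "
            f"{sum(1 for r in self.records if r.entered_wrong_branch)}",
            f"corrections: {sum(1 for r in self.records if r.corrected)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# perception (cached: identical oscillator configs recur every visit)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _recognized_code(
    drive_code: float, lam: float, B: float, As: float, t_end: float, dt: float,
    bank_codes: tuple,
) -> float | None:
    bank = default_bank(lam=lam, codes=bank_codes, B=B)
    responses = bank_response(bank, drive_code, t_end=t_end, dt=dt, As=As)
    idx = recognize_landmark(responses)
    return float(bank_codes[idx]) if idx is not None else None


def perceive(
    agent: AgentState,
    cmap: CognitiveMap,
    lam: float = 0.2,
    B: float = 1.5,
    As: float = 1.0,
    t_end: float = 80.0,
    dt: float = 0.005,
) -> float | None:
    """Recognised frequency code of the landmark at the agent's position.

    Returns ``None`` between landmarks, for distractor/wrong-path landmarks
    (not stored in the bank), or when the bank fails to resonate (AD).
    """
    lm = cmap.landmark_at(*agent.position)
    if lm is None:
        return None
    bank_codes = tuple(l.freq_code for l in cmap.route_landmarks())
    return _recognized_code(lm.freq_code, lam, B, As, t_end, dt, bank_codes)


def check_expectation(agent: AgentState, recognized: float | None) -> str:
    """Compare a recognised code against the next-subgoal buffer: match/mismatch."""
    if agent.stm_next is None:
        raise ValueError("stm_next buffer not loaded")
    if recognized is not None and recognized == agent.stm_next.w_lm_next:
        return "match"
    return "mismatch"


# ---------------------------------------------------------------------------
# weighted path competition (retrieval failure)
# ---------------------------------------------------------------------------


def _turn_angle(heading: tuple[float, float], direction: tuple[float, float]) -> float:
    h = math.atan2(heading[1], heading[0])
    d = math.atan2(direction[1], direction[0])
    return abs((d - h + math.pi) % (2 * math.pi) - math.pi)


def choose_by_competition(
    cmap: CognitiveMap,
    current_id: int,
    lost_code: float | None = None,
    prev_heading: tuple[float, float] = (1.0, 0.0),
    rng: np.random.Generator | None = None,
) -> int | None:
    """Pick the next landmark by weighted competition among outgoing paths.

    Candidates are the landmarks connected to ``current_id``; each is
    weighted ``1 / (1 + |code - lost_code|)``.  With no lost code all
    weights are equal and the fall-back ordering applies: smallest turning
    angle from ``prev_heading``, then lowest id.  Pass a seeded ``rng`` to
    sample proportionally to the weights instead (logged).  Returns ``None``
    when there is no outgoing path (the caller records "stuck").
    """
    candidates = cmap.neighbours(current_id)
    if not candidates:
        return None
    if lost_code is not None:
        weights = np.array(
            [1.0 / (1.0 + abs(cmap.code_of(c) - lost_code)) for c in candidates]
        )
    else:
        weights = np.ones(len(candidates))
    if rng is not None:
        choice = int(rng.choice(len(candidates), p=weights / weights.sum()))
        log.info("competition (seeded RNG) chose landmark %d", candidates[choice])
        return candidates[choice]
    top = np.flatnonzero(np.isclose(weights, weights.max(), rtol=1e-12, atol=0.0))
    if len(top) == 1:
        return candidates[int(top[0])]
    here = cmap.landmark(current_id)

    def sort_key(i: int):
        lm = cmap.landmark(candidates[i])
        direction = (lm.x - here.x, lm.y - here.y)
        return (_turn_angle(prev_heading, direction), candidates[i])

    return candidates[int(min(top, key=sort_key))]


# ---------------------------------------------------------------------------
# the closed loop
# ---------------------------------------------------------------------------


class Navigator:
    """Binds a cognitive map, a rule base and a scenario config into one run."""

    def __init__(
        self,
        config: ScenarioConfig,
        cmap: CognitiveMap | None = None,
        rulebase: FuzzyRuleBase | None = None,
    ):
        self.cmap = cmap if cmap is not None else build_default_map()
        config.validate(self.cmap)
        self.config = config
        self.rulebase = (
            rulebase if rulebase is not None else build_complete_rulebase(self.cmap)
        )
        self.rng = (
            np.random.default_rng(config.seed)
            if config.competition_rng and config.seed is not None
            else (np.random.default_rng() if config.competition_rng else None)
        )

    # -- helpers ---------------------------------------------------------

    def _perceive(self, agent: AgentState) -> float | None:
        c = self.config
        return perceive(agent, self.cmap, lam=c.lam, B=c.B, As=c.As,
                        t_end=c.t_end, dt=c.dt)

    def _memory_row(self, next_id: int, here: tuple[float, float]) -> CognitiveMapRow:
        if next_id in self.cmap.lesioned:
            return CognitiveMapRow(0.0, 0.0, 0.0, 0.0, 0.0)
        lm = self.cmap.landmark(next_id)
        return CognitiveMapRow(lm.x, lm.y, lm.freq_code, here[0], here[1])

    def _shift_stm(self, agent: AgentState, row: CognitiveMapRow | None) -> None:
        agent.stm_prev = agent.stm_next
        agent.stm_next = row

    def _move(self, agent: AgentState, next_id: int) -> None:
        lm = self.cmap.landmark(next_id)
        x0, y0 = agent.position
        if (lm.x, lm.y) != (x0, y0):
            agent.heading = (lm.x - x0, lm.y - y0)
        agent.position = (lm.x, lm.y)

    @staticmethod
    def _row_tuple(row: CognitiveMapRow | None):
        return tuple(float(v) for v in row.as_array()) if row is not None else None

    # -- main loop -------------------------------------------------------

    def run(self) -> NavigationTrace:
        c, cmap = self.config, self.cmap
        start_lm = cmap.landmark(c.start)
        goal_lm = cmap.landmark(c.goal)
        goal_code = c.goal_code if c.goal_code is not None else goal_lm.freq_code
        route_len = abs(c.goal - c.start) + 1
        max_steps = c.max_steps if c.max_steps is not None else 4 * max(route_len, 1)

        agent = AgentState(
            position=(start_lm.x, start_lm.y),
            heading=tuple(c.initial_heading),
        )
        trace = NavigationTrace()
        step = 0
        while True:
            if agent.position == (goal_lm.x, goal_lm.y) and not agent.on_wrong_path:
                trace.outcome = "goal"
                break
            if step >= max_steps:
                trace.outcome = "lost"
                break
            att = c.attention_at(step)
            agent.attention = att
            lm = cmap.landmark_at(*agent.position)
            corrected = False

            if agent.on_wrong_path:
                if att < ATTENTION_THRESHOLD:
                    # attention still low: the agent remains on the branch
                    trace.records.append(
                        TraceRecord(
                            step, *agent.position,
                            landmark_id=lm.id if lm else None,
                            recognized_code=None, attention=att,
                            raw_output=None, snapped_id=None, stayed=True,
                            stm_next=self._row_tuple(agent.stm_next),
                            stm_prev=self._row_tuple(agent.stm_prev),
                        )
                    )
                    step += 1
                    continue
                # attention recovered: backtrack to the decision landmark
                agent.position = agent.decision_position
                agent.on_wrong_path = False
                corrected = True
                lm = cmap.landmark_at(*agent.position)

            recognized = self._perceive(agent)
            wrong_path_message = False
            if agent.stm_next is not None and not agent.stm_next.is_zero():
                wrong_path_message = check_expectation(agent, recognized) == "mismatch"

            retrieval_failed = False
            if recognized is not None and lm is not None:
                here_code = (
                    c.here_code if step == 0 and c.here_code is not None else recognized
                )
                agent.here_code = here_code
                res = infer_next_step(
                    self.rulebase, here_code, goal_code, att,
                    cmap=cmap, units="code",
                )
                next_id, raw = res.snapped_id, res.raw
                if next_id in cmap.lesioned:
                    # the retrieved row is erased: weighted path competition
                    lost = cmap.code_of(next_id)
                    alt = choose_by_competition(
                        cmap, lm.id, lost_code=lost,
                        prev_heading=agent.heading, rng=self.rng,
                    )
                    if alt is None:
                        trace.records.append(
                            TraceRecord(step, *agent.position, lm.id, recognized,
                                        att, raw, None, stuck=True,
                                        wrong_path_message=wrong_path_message)
                        )
                        trace.outcome = "stuck"
                        break
                    next_id = alt
            else:
                # nothing recognised (AD regime or off-map landmark):
                # retrieval fails, competition decides
                raw = None
                retrieval_failed = True
                lost = (
                    agent.stm_next.w_lm_next
                    if agent.stm_next is not None and not agent.stm_next.is_zero()
                    else None
                )
                next_id = choose_by_competition(
                    cmap, lm.id if lm else -1, lost_code=lost,
                    prev_heading=agent.heading, rng=self.rng,
                )
                if next_id is None:
                    trace.records.append(
                        TraceRecord(step, *agent.position,
                                    lm.id if lm else None, recognized, att,
                                    None, None, stuck=True,
                                    wrong_path_message=wrong_path_message)
                    )
                    trace.outcome = "stuck"
                    break

            # a failed retrieval loads nothing meaningful into the buffer
            row = (
                CognitiveMapRow(0.0, 0.0, 0.0, 0.0, 0.0)
                if retrieval_failed
                else self._memory_row(next_id, agent.position)
            )
            self._shift_stm(agent, row)
            entered_branch = cmap.landmark(next_id).role == ROLE_WRONG_PATH
            if entered_branch and not retrieval_failed:
                # the low-attention rule sent the agent onto the branch; it
                # will dwell there until attention recovers, then backtrack.
                # A competition-driven wander onto a branch carries no such
                # awareness and no correction is scheduled.
                agent.decision_position = agent.position
                agent.on_wrong_path = True
            self._move(agent, next_id)
            trace.records.append(
                TraceRecord(
                    step, *agent.position,
                    landmark_id=next_id,
                    recognized_code=recognized,
                    attention=att,
                    raw_output=raw,
                    snapped_id=next_id,
                    wrong_path_message=wrong_path_message,
                    entered_wrong_branch=entered_branch,
                    corrected=corrected,
                    stm_next=self._row_tuple(agent.stm_next),
                    stm_prev=self._row_tuple(agent.stm_prev),
                )
            )
            step += 1
        return trace


def run_scenario(
    config: ScenarioConfig | str,
    cmap: CognitiveMap | None = None,
    rulebase: FuzzyRuleBase | None = None,
) -> NavigationTrace:
    """Run a scenario (a config object or a preset name) to completion."""
    if isinstance(config, str):
        config = load_preset(config)
    return Navigator(config, cmap=cmap, rulebase=rulebase).run()
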