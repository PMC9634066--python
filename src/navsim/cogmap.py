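"""Cognitive-map data model: landmarks, routes, and the long-term-memory matrix.

The spatial long-term memory of the agent is represented by a set of landmarks
on an orthogonal grid plus, per learned route, one matrix row per step holding
the coordinates and identification frequency of the next expected landmark
together with the agent's own coordinates at that step::

    [x_lm_next, y_lm_next, w_lm_next, x_motor, y_motor]

Landmarks carry a symbolic *frequency code* (``freq_code``): a positive scalar
standing in for the dominant harmonic by which the what-stream identifies the
landmark.  On the default map the six route landmarks LM1..LM6 carry codes
4..9 and each turning point LM1..LM5 has an attached wrong-path branch
landmark LM7..LM11 (codes 10..14) that a low-attention agent may enter.

Amnesia (e.g. hippocampal atrophy in Alzheimer's disease) is modelled by
*lesioning* landmarks: their memory-matrix rows are zeroed so the landmark can
no longer be retrieved, although it still exists in the environment and still
emits its stimulus.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Landmark",
    "CognitiveMapRow",
    "CognitiveMap",
    "build_default_map",
    "lesion",
    "read_map",
    "write_map",
]

MAP_FORMAT_VERSION = 1

ROLE_ROUTE = "route"
ROLE_WRONG_PATH = "wrong_path"
ROLE_DISTRACTOR = "distractor"
_ROLES = (ROLE_ROUTE, ROLE_WRONG_PATH, ROLE_DISTRACTOR)


@dataclass(frozen=True)
class Landmark:
    """A landmark: identity, grid coordinates and symbolic frequency code."""

    id: int
    x: float
    y: float
    freq_code: float
    role: str = ROLE_ROUTE

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"landmark id must be positive, got {self.id}")
        if self.freq_code <= 0:
            raise ValueError(
                f"landmark {self.id}: freq_code must be positive, got {self.freq_code}"
            )
        if self.role not in _ROLES:
            raise ValueError(f"landmark {self.id}: unknown role {self.role!r}")


@dataclass
class CognitiveMapRow:
    """One step of a learned route in the long-term-memory matrix."""

    x_lm_next: float
    y_lm_next: float
    w_lm_next: float
    x_motor: float
    y_motor: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_lm_next, self.y_lm_next, self.w_lm_next, self.x_motor, self.y_motor]
        )

    def is_zero(self) -> bool:
        return not np.any(self.as_array())


@dataclass
class CognitiveMap:
    """Landmark set, named routes, wrong-path branches and the memory matrix.

    ``rows[name][i]`` is the matrix row for step i of route ``name``, i.e. the
    step from ``routes[name][i]`` to ``routes[name][i+1]``.
    """

    landmarks: dict[int, Landmark]
    routes: dict[str, list[int]] = field(default_factory=dict)
    wrong_branches: dict[int, int] = field(default_factory=dict)
    rows: dict[str, list[CognitiveMapRow]] = field(default_factory=dict)
    lesioned: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for lid, lm in self.landmarks.items():
            if lid != lm.id:
                raise ValueError(f"landmark key {lid} != landmark id {lm.id}")
        for name, seq in self.routes.items():
            for lid in seq:
                if lid not in self.landmarks:
                    raise ValueError(f"route {name!r} references unknown landmark {lid}")
        for a, b in self.wrong_branches.items():
            if a not in self.landmarks or b not in self.landmarks:
                raise ValueError(f"wrong branch {a}->{b} references unknown landmark")
        if not self.rows:
            self.rows = {name: self._build_rows(name) for name in self.routes}

    def _build_rows(self, route_name: str) -> list[CognitiveMapRow]:
        seq = self.routes[route_name]
        rows = []
        for a, b in zip(seq[:-1], seq[1:]):
            la, lb = self.landmarks[a], self.landmarks[b]
            rows.append(CognitiveMapRow(lb.x, lb.y, lb.freq_code, la.x, la.y))
        return rows

    # -- lookups ---------------------------------------------------------

    def landmark(self, lid: int) -> Landmark:
        try:
            return self.landmarks[lid]
        except KeyError:
            raise KeyError(f"unknown landmark id {lid}") from None

    def route_landmarks(self) -> list[Landmark]:
        return sorted(
            (lm for lm in self.landmarks.values() if lm.role == ROLE_ROUTE),
            key=lambda lm: lm.id,
        )

    def landmark_at(self, x: float, y: float) -> Landmark | None:
        for lm in self.landmarks.values():
            if lm.x == x and lm.y == y:
                return lm
        return None

    def code_of(self, lid: int) -> float:
        return self.landmark(lid).freq_code

    def id_for_code(self, code: float) -> int | None:
        """Landmark id whose code matches ``code`` exactly, if any."""
        for lm in self.landmarks.values():
            if lm.freq_code == code:
                return lm.id
        return None

    def code_to_id(self, code: float) -> float:
        """Continuous frequency-code -> landmark-id axis conversion.

        Route landmark codes are affine in the id (code = id + 3 on the
        default map); the fit is over route landmarks so a perceived code with
        jitter (e.g. 4.2) maps to a fractional position on the id axis (1.2).
        """
        lms = self.route_landmarks()
        if len(lms) < 2:
            return float(lms[0].id) if lms else float(code)
        ids = np.array([lm.id for lm in lms], dtype=float)
        codes = np.array([lm.freq_code for lm in lms], dtype=float)
        slope, intercept = np.polyfit(codes, ids, 1)
        return float(slope * code + intercept)

    def id_to_code(self, lid: float) -> float:
        lms = self.route_landmarks()
        if len(lms) < 2:
            return float(lms[0].freq_code) if lms else float(lid)
        ids = np.array([lm.id for lm in lms], dtype=float)
        codes = np.array([lm.freq_code for lm in lms], dtype=float)
        slope, intercept = np.polyfit(ids, codes, 1)
        return float(slope * lid + intercept)

    # -- topology --------------------------------------------------------

    def neighbours(self, lid: int) -> list[int]:
        """Landmarks connected to ``lid`` by a route segment or a branch."""
        out: set[int] = set()
        for seq in self.routes.values():
            for a, b in zip(seq[:-1], seq[1:]):
                if a == lid:
                    out.add(b)
                if b == lid:
                    out.add(a)
        for a, b in self.wrong_branches.items():
            if a == lid:
                out.add(b)
            if b == lid:
                out.add(a)
        return sorted(out)

    def validate_contiguity(self) -> None:
        """Check consecutive route landmarks share a grid line (orthogonal segments)."""
        for name, seq in self.routes.items():
            for a, b in zip(seq[:-1], seq[1:]):
                la, lb = self.landmarks[a], self.landmarks[b]
                if la.x != lb.x and la.y != lb.y:
                    raise ValueError(
                        f"route {name!r}: landmarks {a} and {b} are not connected "
                        f"by an axis-aligned grid segment"
                    )

    def row_for_step(self, route_name: str, step: int) -> CognitiveMapRow:
        return self.rows[route_name][step]


# ---------------------------------------------------------------------------
# default fixture map
# ---------------------------------------------------------------------------

#: Orthogonal staircase geometry for the six-landmark route.  The turning-point
#: coordinates are a repo convention (config-overridable); only the topology
#: and the frequency codes carry model content.
DEFAULT_ROUTE_COORDS: dict[int, tuple[float, float]] = {
    1: (0, 0),
    2: (4, 0),
    3: (4, 3),
    4: (7, 3),
    5: (7, 6),
    6: (10, 6),
}

#: Branch landmarks continue straight through each turning point (the path a
#: low-attention agent takes instead of turning).
DEFAULT_BRANCH_COORDS: dict[int, tuple[float, float]] = {
    7: (0, 2),
    8: (6, 0),
    9: (4, 5),
    10: (9, 3),
    11: (7, 8),
}

#: Wrong-path attachment at the decision landmarks.
DEFAULT_WRONG_BRANCHES: dict[int, int] = {1: 7, 2: 8, 3: 9, 4: 10, 5: 11}

#: Route landmark id -> identification frequency code (codes 4..9 for LM1..6,
#: extended affinely to the branch landmarks).
CODE_OFFSET = 3


def build_default_map(
    n_route: int = 6,
    route_coords: dict[int, tuple[float, float]] | None = None,
    branch_coords: dict[int, tuple[float, float]] | None = None,
) -> CognitiveMap:
    """Build the default six-landmark map with wrong-path branches.

    Route landmarks 1..6 carry frequency codes 4..9; branch landmarks 7..11
    attach at turning points 1..5 (code = id + 3 throughout).  Two routes are
    learned: ``route1`` LM1->LM6 and ``route2`` LM4->LM1.  Coordinates are
    overridable for alternative geometries.
    """
    route_coords = dict(DEFAULT_ROUTE_COORDS if route_coords is None else route_coords)
    branch_coords = dict(DEFAULT_BRANCH_COORDS if branch_coords is None else branch_coords)

    landmarks: dict[int, Landmark] = {}
    for lid in range(1, n_route + 1):
        x, y = route_coords[lid]
        landmarks[lid] = Landmark(lid, x, y, lid + CODE_OFFSET, ROLE_ROUTE)
    wrong_branches: dict[int, int] = {}
    if n_route == 6:
        for dec, br in DEFAULT_WRONG_BRANCHES.items():
            x, y = branch_coords[br]
            landmarks[br] = Landmark(br, x, y, br + CODE_OFFSET, ROLE_WRONG_PATH)
            wrong_branches[dec] = br

    routes: dict[str, list[int]] = {}
    if n_route >= 2:
        routes["route1"] = list(range(1, n_route + 1))
    if n_route >= 4:
        routes["route2"] = [4, 3, 2, 1]

    m = CognitiveMap(landmarks=landmarks, routes=routes, wrong_branches=wrong_branches)
    m.validate_contiguity()
    return m


# ---------------------------------------------------------------------------
# lesioning
# ---------------------------------------------------------------------------


def lesion(cmap: CognitiveMap, landmark_ids) -> CognitiveMap:
    """Return a copy of ``cmap`` with memory rows for ``landmark_ids`` zeroed.

    The landmarks stay in the environment (they still emit stimuli) but their
    entries in the long-term-memory matrix are erased, so retrieval of the
    corresponding step fails.  Idempotent; unknown ids raise ``KeyError``.
    """
    ids = set(landmark_ids)
    for lid in ids:
        if lid not in cmap.landmarks:
            raise KeyError(f"cannot lesion unknown landmark id {lid}")
    out = copy.deepcopy(cmap)
    out.lesioned |= ids
    for name, seq in out.routes.items():
        for step, target in enumerate(seq[1:]):
            if target in out.lesioned:
                out.rows[name][step] = CognitiveMapRow(0.0, 0.0, 0.0, 0.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# serialization (YAML, versioned schema)
# ---------------------------------------------------------------------------

_LM_FIELDS = ("id", "x", "y", "freq_code", "role")


def write_map(path, cmap: CognitiveMap) -> None:
    doc = {
        "format_version": MAP_FORMAT_VERSION,
        "landmarks": [
            {
                "id": lm.id,
                "x": lm.x,
                "y": lm.y,
                "freq_code": lm.freq_code,
                "role": lm.role,
            }
            for lm in sorted(cmap.landmarks.values(), key=lambda lm: lm.id)
        ],
        "routes": {name: list(seq) for name, seq in cmap.routes.items()},
        "wrong_branches": {int(k): int(v) for k, v in cmap.wrong_branches.items()},
        "lesioned": sorted(cmap.lesioned),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_map(path) -> CognitiveMap:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # carries line/column context
            raise ValueError(f"malformed map file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"malformed map file {path}: expected a mapping at top level")
    version = doc.get("format_version")
    if version != MAP_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format_version {version!r}")
    landmarks = {}
    for i, entry in enumerate(doc.get("landmarks", [])):
        missing = [f for f in _LM_FIELDS if f not in entry]
        if missing:
            raise ValueError(
                f"{path}: landmark entry {i} missing field(s) {', '.join(missing)}"
            )
        lm = Landmark(
            int(entry["id"]),
            float(entry["x"]),
            float(entry["y"]),
            float(entry["freq_code"]),
            str(entry["role"]),
        )
        landmarks[lm.id] = lm
    cmap = CognitiveMap(
        landmarks=landmarks,
        routes={str(k): [int(i) for i in v] for k, v in (doc.get("routes") or {}).items()},
        wrong_branches={int(k): int(v) for k, v in (doc.get("wrong_branches") or {}).items()},
    )
    lesioned = doc.get("lesioned") or []
    if lesioned:
        cmap = lesion(cmap, [int(i) for i in lesioned])
    return cmap
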