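"""View specifications: anatomical letters, panel grids, rotation frames.

A view is requested as a single anatomical letter ('L', 'R', 'A', 'P',
'S', 'I'), a string of letters (one panel each), a list of such strings
(one row each), a ``'preset-N'`` shorthand, or an explicit
(azimuth, elevation) 2-tuple.  A lowercase ``'s'`` anywhere requests the
force-directed spring-layout companion panel.  Two letters plus a
``frames`` count interpolate the camera between the two views.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from .data_model import EdgeTable, NodeTable

# Fixed camera convention under RAS world axes (matplotlib azim/elev degrees).
LETTER_ANGLES: dict[str, tuple[float, float]] = {
    "L": (180.0, 0.0),
    "R": (0.0, 0.0),
    "A": (90.0, 0.0),
    "P": (-90.0, 0.0),
    "S": (-90.0, 90.0),
    "I": (-90.0, -90.0),
}

PRESETS: dict[str, list[str]] = {
    "preset-3": ["LSR"],
    "preset-4": ["LPRA"],
    "preset-6": ["LRA", "PSI"],
}
# preset-9: the six anatomical views plus three oblique angles
_OBLIQUES = [(45.0, 30.0), (-45.0, 30.0), (135.0, 30.0)]

SPRING_MARKER = "s"


@dataclass(frozen=True)
class CameraAngle:
    """Camera azimuth/elevation in degrees; azimuth normalized to (-180, 180]."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.azimuth) and np.isfinite(self.elevation)):
            raise ValueError("camera angles must be finite")
        az = ((self.azimuth + 180.0) % 360.0) - 180.0
        if az == -180.0:
            az = 180.0
        object.__setattr__(self, "azimuth", float(az))
        object.__setattr__(self, "elevation", float(self.elevation))


Panel = Union[CameraAngle, str]  # str is the spring-layout marker


@dataclass
class ViewSpec:
    """Grid of panels: each an anatomical camera angle or the spring marker."""

    rows: list[list[Panel]]

    def __post_init__(self) -> None:
        if not self.rows or any(len(r) == 0 for r in self.rows):
            raise ValueError("view grid needs >= 1 row with >= 1 panel each")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return max(len(r) for r in self.rows)

    @property
    def total_panels(self) -> int:
        return sum(len(r) for r in self.rows)

    def flat(self) -> list[Panel]:
        return [p for row in self.rows for p in row]


def letter_to_angle(letter: str) -> CameraAngle:
    """Fixed anatomical-letter -> camera-angle mapping (RAS convention)."""
    if letter not in LETTER_ANGLES:
        raise ValueError(f"unknown view letter {letter!r}; choose one of "
                         f"{sorted(LETTER_ANGLES)} (or 's' for a spring layout)")
    return CameraAngle(*LETTER_ANGLES[letter])


def interpolate_angles(a: CameraAngle, b: CameraAngle, frames: int) -> list[CameraAngle]:
    """``frames`` cameras linearly rotating a -> b along the shorter arc.

    Endpoints are included exactly.  A 180-degree azimuth tie breaks
    toward decreasing azimuth.
    """
    if frames < 2:
        raise ValueError(f"frames must be >= 2, got {frames}")
    daz = b.azimuth - a.azimuth
    if daz > 180.0 or (daz == 180.0):
        daz -= 360.0  # shorter arc / tie toward decreasing azimuth
    elif daz < -180.0:
        daz += 360.0
    t = np.linspace(0.0, 1.0, frames)
    out = [CameraAngle(a.azimuth + daz * tk,
                       a.elevation + (b.elevation - a.elevation) * tk) for tk in t]
    out[0], out[-1] = CameraAngle(a.azimuth, a.elevation), CameraAngle(b.azimuth, b.elevation)
    return out


def _parse_letter_string(s: str) -> list[Panel]:
    panels: list[Panel] = []
    for ch in s:
        if ch == SPRING_MARKER:
            panels.append(SPRING_MARKER)
        else:
            panels.append(letter_to_angle(ch))
    return panels


def parse_view(view: Union[str, Sequence, tuple],
               frames: Optional[int] = None) -> ViewSpec:
    """Parse any accepted view form into a panel grid.

    Grammar: a letter string over {S,I,P,A,L,R,s} (1 x k grid), a list of
    such strings (one row each), ``'preset-N'``, or a numeric (azimuth,
    elevation) 2-tuple.  ``frames`` requires exactly two letters and
    expands them into a 1 x frames rotation sequence.
    """
    if isinstance(view, str) and view.startswith("preset-"):
        if frames is not None:
            raise ValueError("frames cannot be combined with a preset view")
        if view in PRESETS:
            return ViewSpec([_parse_letter_string(row) for row in PRESETS[view]])
        if view == "preset-9":
            rows = [_parse_letter_string(r) for r in PRESETS["preset-6"]]
            rows.append([CameraAngle(*ang) for ang in _OBLIQUES])
            return ViewSpec(rows)
        raise ValueError(f"unknown preset {view!r}; available: "
                         f"{sorted([*PRESETS, 'preset-9'])}")

    if isinstance(view, str):
        if frames is not None:
            letters = [ch for ch in view if ch != SPRING_MARKER]
            if len(view) != 2 or len(letters) != 2:
                raise ValueError("frames requires a view of exactly two "
                                 f"anatomical letters, got {view!r}")
            seq = interpolate_angles(letter_to_angle(view[0]),
                                     letter_to_angle(view[1]), frames)
            return ViewSpec([list(seq)])
        if not view:
            raise ValueError("view string is empty")
        return ViewSpec([_parse_letter_string(view)])

    if isinstance(view, (tuple, list)) and len(view) == 2 and \
            all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in view):
        if frames is not None:
            raise ValueError("frames requires two anatomical letters, not a numeric 2-tuple")
        return ViewSpec([[CameraAngle(float(view[0]), float(view[1]))]])

    if isinstance(view, (list, tuple)):
        if frames is not None:
            raise ValueError("frames cannot be combined with a multi-row view list")
        if not view or not all(isinstance(r, str) and r for r in view):
            raise ValueError(f"a view list must contain non-empty letter strings, got {view!r}")
        return ViewSpec([_parse_letter_string(r) for r in view])

    raise TypeError(f"unsupported view specification of type {type(view).__name__}")


def spring_layout(nodes: NodeTable, edges: Optional[EdgeTable],
                  seed: int = 42) -> np.ndarray:
    """Deterministic force-directed (Fruchterman-Reingold) 2D embedding.

    Returns an (N, 2) array in node_id order; positions depend only on
    the network topology, edge weights, and the seed.
    """
    if nodes.n == 0:
        raise ValueError("spring layout needs >= 1 node")
    g = nx.Graph()
    ids = [int(i) for i in nodes.data["node_id"]]
    g.add_nodes_from(ids)
    if edges is not None:
        for i, j, w in zip(edges.data["i"], edges.data["j"], edges.data["weight"]):
            g.add_edge(int(i), int(j), weight=float(w))
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    return np.array([pos[i] for i in ids], dtype=float)
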