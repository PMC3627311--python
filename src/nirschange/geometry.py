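"""Optode lattice geometry and measurement-channel derivation.

A probe pad is a rectangular lattice of optodes with source/detector roles
assigned in a checkerboard (top-left node is a source).  Measurement channels
connect one source and one detector:

* *short* channels join lattice-adjacent optodes, at the nominal
  source-detector separation (25 mm for infant pads, 30 mm for adult pads);
* *long* channels join optodes offset by one row and two columns, at
  ``spacing * sqrt(5)`` (~55.9 mm for a 25 mm pad), available only on
  instruments that record non-adjacent pairs.

One pad is placed over each temporal area, so a montage carries a left and a
right pad with mirrored channel numbering; channel *k* on the left pad and
channel *k* on the right pad are hemispheric counterparts.  Channel numbering
is deterministic (row-major over lattice nodes, right neighbour before down
neighbour) and region-of-interest membership is configurable rather than tied
to any particular printed figure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Channel",
    "ProbeLayout",
    "Montage",
    "build_layout",
    "build_montage",
    "hemispheric_counterpart",
    "layout_to_json",
    "layout_from_json",
]

SOURCE = "source"
DETECTOR = "detector"

#: lattice offsets defining short (adjacent) channels, scanned in this order
_SHORT_OFFSETS = ((0, 1), (1, 0))
#: offsets defining long (non-adjacent, knight's-move) channels
_LONG_OFFSETS = ((1, 2), (1, -2), (2, 1), (2, -1))


@dataclass(frozen=True)
class Channel:
    """A single source-detector measurement channel."""

    id: int
    source: tuple[int, int]
    detector: tuple[int, int]
    distance_mm: float
    kind: str  # "short" | "long"
    hemisphere: str  # "left" | "right"
    roi: bool

    @property
    def key(self) -> tuple[str, int]:
        return (self.hemisphere, self.id)


@dataclass(frozen=True)
class ProbeLayout:
    """One probe pad: the optode lattice plus its derived channels."""

    rows: int
    cols: int
    spacing_mm: float
    hemisphere: str
    include_long: bool
    roi_channels: frozenset[int]
    optode_roles: dict[tuple[int, int], str] = field(compare=False)
    channels: tuple[Channel, ...] = field(compare=False)

    @property
    def short_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "short")

    @property
    def long_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.kind == "long")

    def channel(self, channel_id: int) -> Channel:
        for c in self.channels:
            if c.id == channel_id:
                return c
        raise KeyError(f"channel {channel_id} not in layout")


@dataclass(frozen=True)
class Montage:
    """Mirrored left/right probe pads."""

    left: ProbeLayout
    right: ProbeLayout

    @property
    def channels(self) -> tuple[Channel, ...]:
        return self.left.channels + self.right.channels

    @property
    def hemispheres(self) -> tuple[str, str]:
        return ("left", "right")

    def pad(self, hemisphere: str) -> ProbeLayout:
        if hemisphere == "left":
            return self.left
        if hemisphere == "right":
            return self.right
        raise KeyError(f"unknown hemisphere {hemisphere!r}")

    def channel(self, hemisphere: str, channel_id: int) -> Channel:
        return self.pad(hemisphere).channel(channel_id)

    def roi_channels(self, hemisphere: str) -> tuple[Channel, ...]:
        return tuple(c for c in self.pad(hemisphere).channels if c.roi)


def _role(row: int, col: int) -> str:
    # checkerboard, top-left = source
    return SOURCE if (row + col) % 2 == 0 else DETECTOR


def build_layout(
    rows: int = 2,
    cols: int = 4,
    spacing_mm: float = 25.0,
    include_long: bool = False,
    hemisphere: str = "left",
    roi_channels: Iterable[int] = (4, 6, 7),
) -> ProbeLayout:
    """Build one probe pad and enumerate its measurement channels.

    Channels are numbered from 1, scanning lattice nodes row-major and, for
    each node, taking the right neighbour before the down neighbour; long
    channels (if requested) continue the numbering after the short ones.

    Raises
    ------
    ValueError
        If the lattice is degenerate (fewer than two nodes, or no
        source-detector pair exists).
    """
    if rows < 1 or cols < 1 or spacing_mm <= 0:
        raise ValueError("rows and cols must be >= 1 and spacing positive")
    if hemisphere not in ("left", "right"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")

    roles = {(r, c): _role(r, c) for r in range(rows) for c in range(cols)}
    roi = frozenset(int(k) for k in roi_channels)

    def pair(a: tuple[int, int], b: tuple[int, int]) -> tuple | None:
        if roles[a] == roles[b]:  # same role: not a measurement channel
            return None
        src, det = (a, b) if roles[a] == SOURCE else (b, a)
        return src, det

    channels: list[Channel] = []
    next_id = 1
    for offsets, kind, dist in (
        (_SHORT_OFFSETS, "short", spacing_mm),
        (_LONG_OFFSETS, "long", spacing_mm * math.sqrt(5.0)),
    ):
        if kind == "long" and not include_long:
            continue
        for r in range(rows):
            for c in range(cols):
                for dr, dc in offsets:
                    nb = (r + dr, c + dc)
                    if nb not in roles:
                        continue
                    got = pair((r, c), nb)
                    if got is None:
                        continue
                    src, det = got
                    channels.append(
                        Channel(
                            id=next_id,
                            source=src,
                            detector=det,
                            distance_mm=dist,
                            kind=kind,
                            hemisphere=hemisphere,
                            roi=next_id in roi,
                        )
                    )
                    next_id += 1

    if not channels:
        raise ValueError("no channels derivable from this lattice")
    return ProbeLayout(
        rows=rows,
        cols=cols,
        spacing_mm=spacing_mm,
        hemisphere=hemisphere,
        include_long=include_long,
        roi_channels=roi,
        optode_roles=roles,
        channels=tuple(channels),
    )


def build_montage(
    rows: int = 2,
    cols: int = 4,
    spacing_mm: float = 25.0,
    include_long: bool = False,
    roi_channels: Iterable[int] = (4, 6, 7),
) -> Montage:
    """Build mirrored left/right pads with identical channel numbering."""
    roi = tuple(roi_channels)
    return Montage(
        left=build_layout(rows, cols, spacing_mm, include_long, "left", roi),
        right=build_layout(rows, cols, spacing_mm, include_long, "right", roi),
    )


def hemispheric_counterpart(channel_id: int, montage: Montage) -> int:
    """Mirror channel ``channel_id`` onto the opposite pad.

    With mirrored numbering the counterpart of left channel *k* is right
    channel *k*; the map is an involution.  Raises ``KeyError`` if the id does
    not exist on both pads.
    """
    left_ids = {c.id for c in montage.left.channels}
    right_ids = {c.id for c in montage.right.channels}
    if channel_id not in left_ids or channel_id not in right_ids:
        raise KeyError(f"channel {channel_id} not present in both hemispheres")
    return channel_id


def layout_to_json(obj: ProbeLayout | Montage) -> str:
    """Serialize a pad or montage to a JSON document."""
    if isinstance(obj, Montage):
        return json.dumps(
            {
                "montage": True,
                "left": json.loads(layout_to_json(obj.left)),
                "right": json.loads(layout_to_json(obj.right)),
            },
            indent=2,
        )
    return json.dumps(
        {
            "rows": obj.rows,
            "cols": obj.cols,
            "spacing_mm": obj.spacing_mm,
            "hemisphere": obj.hemisphere,
            "include_long": obj.include_long,
            "roi_channels": sorted(obj.roi_channels),
            "nodes": [
                {"row": r, "col": c, "role": role}
                for (r, c), role in sorted(obj.optode_roles.items())
            ],
            "channels": [
                {
                    "id": ch.id,
                    "source": list(ch.source),
                    "detector": list(ch.detector),
                    "distance_mm": ch.distance_mm,
                    "kind": ch.kind,
                    "hemisphere": ch.hemisphere,
                    "roi": ch.roi,
                }
                for ch in obj.channels
            ],
        },
        indent=2,
    )


def layout_from_json(text: str) -> ProbeLayout | Montage:
    """Rebuild a pad or montage from :func:`layout_to_json` output."""
    doc = json.loads(text)
    if doc.get("montage"):
        left = _layout_from_doc(doc["left"])
        right = _layout_from_doc(doc["right"])
        return Montage(left=left, right=right)
    return _layout_from_doc(doc)


def _layout_from_doc(doc: dict) -> ProbeLayout:
    return build_layout(
        rows=doc["rows"],
        cols=doc["cols"],
        spacing_mm=doc["spacing_mm"],
        include_long=doc["include_long"],
        hemisphere=doc["hemisphere"],
        roi_channels=doc["roi_channels"],
    )
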