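"""Screen geometry of the mouse-tracking task.

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward (the convention of the recorded cursor samples). The
start box sits in the lower half of the screen; the four response boxes sit
in the upper half, in two colour pairs whose boxes mirror each other about
the vertical midline. Downstream alignment re-anchors trajectories to
task-centric coordinates, so no axis flip is ever applied to raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

Point = tuple[float, float]


@dataclass(frozen=True)
class ScreenLayout:
    """Positions of the start box and the four response boxes."""

    screen_size: Point = (1920.0, 1080.0)
    start_center: Point = (960.0, 935.0)
    start_half_size: Point = (90.0, 45.0)
    response_centers: dict[str, Point] = field(
        default_factory=lambda: {
            "red": (270.0, 135.0),
            "blue": (470.0, 135.0),
            "yellow": (1450.0, 135.0),
            "green": (1650.0, 135.0),
        }
    )
    response_half_size: Point = (130.0, 65.0)
    #: Colour pairs whose boxes mirror about the vertical midline; a stimulus
    #: ink colour always competes with its pair partner.
    pairs: tuple[tuple[str, str], ...] = (("red", "green"), ("blue", "yellow"))

    def __post_init__(self) -> None:
        w, h = self.screen_size
        mid_x = w / 2.0
        if len(self.response_centers) != 4:
            raise ConfigError("response_centers: exactly four response boxes required")
        for a, b in self.pairs:
            for colour in (a, b):
                if colour not in self.response_centers:
                    raise ConfigError(f"pairs: unknown colour {colour!r}")
            (xa, ya), (xb, yb) = self.response_centers[a], self.response_centers[b]
            if abs((xa - mid_x) + (xb - mid_x)) > 1e-6 or abs(ya - yb) > 1e-6:
                raise ConfigError(
                    f"pairs: boxes for {a!r}/{b!r} must mirror about the vertical midline"
                )
        sx, sy = self.start_center
        for colour, (x, y) in self.response_centers.items():
            hx, hy = self.response_half_size
            if not (hx <= x <= w - hx and hy <= y <= h - hy):
                raise ConfigError(f"response_centers: box {colour!r} outside screen bounds")
            if y >= sy:
                raise ConfigError(
                    f"start_center: start box must lie below response box {colour!r}"
                )
        hx, hy = self.start_half_size
        if not (hx <= sx <= w - hx and hy <= sy <= h - hy):
            raise ConfigError("start_center: start box outside screen bounds")

    @property
    def colours(self) -> tuple[str, ...]:
        return tuple(self.response_centers)

    def pair_partner(self, colour: str) -> str:
        """The colour whose box mirrors ``colour``'s box."""
        for a, b in self.pairs:
            if colour == a:
                return b
            if colour == b:
                return a
        raise ConfigError(f"unknown colour {colour!r}")

    def nearest_box(self, point: Point) -> str:
        """Response box whose center is closest to ``point``."""
        colours = list(self.response_centers)
        centers = np.array([self.response_centers[c] for c in colours])
        d = np.linalg.norm(centers - np.asarray(point, dtype=float), axis=1)
        return colours[int(np.argmin(d))]

    def to_dict(self) -> dict:
        return {
            "screen_size": list(self.screen_size),
            "start_center": list(self.start_center),
            "start_half_size": list(self.start_half_size),
            "response_centers": {c: list(p) for c, p in self.response_centers.items()},
            "response_half_size": list(self.response_half_size),
            "pairs": [list(p) for p in self.pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenLayout":
        kwargs = {}
        for key in (
            "screen_size",
            "start_center",
            "start_half_size",
            "response_half_size",
        ):
            if key in d:
                kwargs[key] = tuple(float(v) for v in d[key])
        if "response_centers" in d:
            kwargs["response_centers"] = {
                c: tuple(float(v) for v in p) for c, p in d["response_centers"].items()
            }
        if "pairs" in d:
            kwargs["pairs"] = tuple(tuple(p) for p in d["pairs"])
        return cls(**kwargs)


def default_layout() -> ScreenLayout:
    """The study layout on a 1920x1080 screen."""
    return ScreenLayout()
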