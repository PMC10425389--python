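"""Axis-aligned rectangles on 0-based, row-major pixel grids.

All rectangles are half-open: a ``Rect(row0, col0, height, width)`` covers rows
``row0 .. row0+height-1`` and columns ``col0 .. col0+width-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeometryError


@dataclass(frozen=True)
class Rect:
    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise GeometryError(f"rectangle must have positive extent, got {self}")

    @property
    def row1(self) -> int:
        return self.row0 + self.height

    @property
    def col1(self) -> int:
        return self.col0 + self.width

    @property
    def area(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.row0 >= 0
            and self.col0 >= 0
            and self.row1 <= shape[0]
            and self.col1 <= shape[1]
        )

    def require_within(self, shape: tuple[int, int], what: str = "rectangle") -> None:
        if not self.within(shape):
            raise GeometryError(
                f"{what} {self} does not fit inside a raster of shape {shape}"
            )

    def intersects(self, other: "Rect") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )
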