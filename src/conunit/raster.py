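"""Single-band landscape rasters on a square projected grid.

A deliberately small container: square cells, metre units, origin at the
lower-left corner. Text I/O uses the ESRI ASCII grid format so fixtures and
pipeline outputs stay plain text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """values[row, col]; row 0 is the NORTH edge (ESRI convention)."""

    values: np.ndarray  # 2-D float array
    x0: float  # west edge (m)
    y0: float  # south edge (m)
    cell: float  # cell size (m)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        return (
            self.x0,
            self.x0 + self.ncol * self.cell,
            self.y0,
            self.y0 + self.nrow * self.cell,
        )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing projected point (x, y)."""
        xmin, xmax, ymin, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = min(int((x - xmin) / self.cell), self.ncol - 1)
        # rows count down from the north edge
        row = min(int((ymax - y) / self.cell), self.nrow - 1)
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_index(x, y)
        return float(self.values[r, c])

    def sample_segment(
        self, x1: float, y1: float, x2: float, y2: float, width_m: float = 0.0
    ) -> np.ndarray:
        """Values of all cells touched by the straight segment, optionally
        buffered to ``width_m`` (total width). Cells are deduplicated; NODATA
        cells are dropped. The segment must lie within the extent."""
        length = float(np.hypot(x2 - x1, y2 - y1))
        step = self.cell / 2.0
        n = max(int(np.ceil(length / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)
        xs = x1 + t * (x2 - x1)
        ys = y1 + t * (y2 - y1)
        if width_m > self.cell:
            # perpendicular offsets across the buffer
            if length == 0:
                nx, ny = 1.0, 0.0
            else:
                nx, ny = -(y2 - y1) / length, (x2 - x1) / length
            offs = np.arange(-width_m / 2.0, width_m / 2.0 + step, step)
            xs = (xs[None, :] + nx * offs[:, None]).ravel()
            ys = (ys[None, :] + ny * offs[:, None]).ravel()
        cells = set()
        for x, y in zip(xs, ys):
            try:
                cells.add(self.cell_index(x, y))
            except ValueError:
                if width_m <= self.cell:
                    raise
                # buffer may poke past the extent; interior samples suffice
                continue
        vals = np.array([self.values[r, c] for r, c in sorted(cells)])
        return vals[vals != NODATA]

    def write_ascii(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncol}\n")
            fh.write(f"nrows {self.nrow}\n")
            fh.write(f"xllcorner {self.x0}\n")
            fh.write(f"yllcorner {self.y0}\n")
            fh.write(f"cellsize {self.cell}\n")
            fh.write(f"NODATA_value {NODATA}\n")
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(values=values, x0=header["xllcorner"], y0=header["yllcorner"],
                   cell=header["cellsize"])
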