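"""Shared log10 body-mass discretization.

The community is resolved on a uniform grid of log10 body mass (grams) with
0.1-wide bins by default.  Each functional group occupies a contiguous,
non-empty sub-range of bins (its *mask*), obtained by snapping the group's
size limits to the nearest bin edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LN10 = np.log(10.0)


@dataclass(frozen=True)
class SizeGrid:
    """Uniform discretization of log10 body mass with per-group active ranges.

    Attributes
    ----------
    log10_edges : ndarray, shape (n_bins + 1,)
        Bin edges in log10 grams, strictly increasing, uniformly spaced.
    bin_width : float
        Spacing of the edges in log10 grams (default 0.1).
    group_slices : dict
        Group name -> ``slice`` into the bin (center) arrays.
    """

    log10_edges: np.ndarray
    bin_width: float
    group_slices: dict = field(default_factory=dict)

    def __post_init__(self):
        edges = np.asarray(self.log10_edges, dtype=float)
        object.__setattr__(self, "log10_edges", edges)
        d = np.diff(edges)
        if edges.size < 2 or np.any(d <= 0):
            raise ValueError("grid edges must be strictly increasing")
        if np.any(np.abs(d - self.bin_width) > 1e-12):
            raise ValueError("grid edges must be uniformly spaced at bin_width")

    @property
    def n_bins(self) -> int:
        return self.log10_edges.size - 1

    @property
    def log10_centers(self) -> np.ndarray:
        return 0.5 * (self.log10_edges[:-1] + self.log10_edges[1:])

    @property
    def w_centers(self) -> np.ndarray:
        """Bin-center body masses (g)."""
        return 10.0 ** self.log10_centers

    @property
    def w_edges(self) -> np.ndarray:
        return 10.0 ** self.log10_edges

    @property
    def dw(self) -> np.ndarray:
        """Mass width of each bin (g): w * ln10 * bin_width (midpoint rule)."""
        return self.w_centers * LN10 * self.bin_width

    def mask(self, group: str) -> np.ndarray:
        """Boolean mask of the bins active for `group`."""
        m = np.zeros(self.n_bins, dtype=bool)
        m[self.group_slices[group]] = True
        return m

    def group_bounds(self, group: str) -> tuple[float, float]:
        """Snapped (w_lo, w_hi) in grams for a group's active range."""
        s = self.group_slices[group]
        return 10.0 ** self.log10_edges[s.start], 10.0 ** self.log10_edges[s.stop]


def _snap(x: float, lo: float, bin_width: float) -> int:
    """Index of the edge nearest to log10-mass x; exact ties snap downward."""
    v = (x - lo) / bin_width
    return int(np.ceil(v - 0.5))


def build_size_grid(lo: float, hi: float, bin_width: float = 0.1,
                    group_ranges: dict | None = None) -> SizeGrid:
    """Build the shared size grid and snap each group's limits onto it.

    Parameters
    ----------
    lo, hi : float
        Grid support in log10 grams.
    bin_width : float
        Bin width in log10 grams; (hi - lo) must be a whole number of bins.
    group_ranges : dict, optional
        Group name -> (log10 w_min, log10 w_max).  Limits are snapped to the
        nearest grid edge (ties downward); the snap error never exceeds half
        a bin.
    """
    if not lo < hi:
        raise ValueError(f"grid range must satisfy lo < hi, got ({lo}, {hi})")
    n = (hi - lo) / bin_width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"grid range ({lo}, {hi}) is not commensurate with bin_width {bin_width}")
    n = int(round(n))
    edges = lo + bin_width * np.arange(n + 1)

    slices = {}
    for name, (glo, ghi) in (group_ranges or {}).items():
        i0 = _snap(glo, lo, bin_width)
        i1 = _snap(ghi, lo, bin_width)
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(
                f"group '{name}' range ({glo}, {ghi}) does not fit on grid "
                f"({lo}, {hi}) with bin_width {bin_width}")
        slices[name] = slice(i0, i1)
    return SizeGrid(log10_edges=edges, bin_width=bin_width, group_slices=slices)
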