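"""Zone assignment, diameter histograms and mode detection.

The medullo-papillary complex is partitioned into zones along its long axis
(zone I = most proximal, the last zone = papillary tip); by default three
equal-thickness zones are used, and five are supported for finer axial
profiles.  Diameter distributions are reported as tubule-count histograms
(left-closed, right-open bins) and as normalized fractions, and distribution
modes are located as strict local maxima of the bin counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DiameterHistogram",
    "zone_labels",
    "assign_zone_positions",
    "assign_zones",
    "build_histogram",
    "find_modes",
    "compare_distributions",
    "plot_histogram",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def zone_labels(n_zones: int) -> list[str]:
    """Roman-numeral zone names, proximal ('I') to papillary tip."""
    if not 1 <= n_zones <= len(_ROMAN):
        raise ValueError(f"n_zones must be in [1, {len(_ROMAN)}]")
    return _ROMAN[:n_zones]


def assign_zone_positions(
    positions_um: np.ndarray, lo_um: float, hi_um: float, n_zones: int = 3
) -> np.ndarray:
    """Map axial positions to zone names by equal partition of ``[lo, hi]``.

    A position exactly on an interior boundary is assigned to the more
    proximal (lower-numbered) zone; zone widths are ``(hi - lo) / n_zones``.
    """
    if hi_um <= lo_um:
        raise ValueError("zero or negative axial extent")
    pos = np.asarray(positions_um, dtype=float)
    width = (hi_um - lo_um) / n_zones
    # ceil(s/width) - 1 puts boundary values into the lower zone
    idx = np.ceil((pos - lo_um) / width - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, n_zones - 1)
    names = np.array(zone_labels(n_zones))
    return names[idx]


def assign_zones(
    measurements: pd.DataFrame,
    organ_axis: np.ndarray,
    axial_extent_um: tuple[float, float],
    n_zones: int = 3,
    centroid_columns: tuple[str, str, str] = ("centroid_z_um", "centroid_y_um", "centroid_x_um"),
) -> pd.DataFrame:
    """Assign each tubule a zone from its centroid position along the organ axis.

    Parameters
    ----------
    measurements : DataFrame
        Per-tubule table carrying physical centroid coordinates (μm, zyx).
    organ_axis : (3,) array_like
        Unit vector of the organ's long axis in ``(z, y, x)`` component order,
        pointing from the proximal face toward the papillary tip.
    axial_extent_um : (lo, hi)
        Range of axial positions (projections onto ``organ_axis``) spanned by
        the organ; split into ``n_zones`` equal intervals.
    n_zones : int
        Number of zones (3 for the standard I/II/III partition; 5 supported).

    Returns a copy of ``measurements`` with the ``zone`` column set.
    """
    axis = np.asarray(organ_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("organ_axis must be nonzero")
    axis = axis / nrm
    out = measurements.copy()
    if len(out) == 0:
        out["zone"] = pd.Series(dtype=object)
        return out
    cz, cy, cx = (out[c].to_numpy(dtype=float) for c in centroid_columns)
    s = cz * axis[0] + cy * axis[1] + cx * axis[2]
    out["zone"] = assign_zone_positions(s, axial_extent_um[0], axial_extent_um[1], n_zones)
    return out


@dataclass
class DiameterHistogram:
    """A binned tubule-diameter distribution.

    Bins are left-closed, right-open ``[edge_i, edge_{i+1})``; ``normalized``
    divides counts by the total in-range count ``n`` (all zeros when empty).
    Diameters at or beyond the last edge are tallied in ``overflow`` rather
    than a bin.
    """

    bin_edges_um: np.ndarray
    counts: np.ndarray
    zone: str = "pooled"
    overflow: int = 0
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges_um.ndim != 1 or len(self.bin_edges_um) < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges_um) - 1:
            raise ValueError("counts/edges length mismatch")
        n = int(self.counts.sum())
        self.normalized = (
            self.counts / n if n > 0 else np.zeros_like(self.counts, dtype=float)
        )

    @property
    def n(self) -> int:
        """Total tubules tallied in-range."""
        return int(self.counts.sum())

    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def build_histogram(
    diameters_um,
    bin_width_um: float = 10.0,
    range_um: tuple[float, float] = (0.0, 100.0),
    zone: str = "pooled",
) -> DiameterHistogram:
    """Histogram tubule diameters into fixed-width bins.

    Values ``>= range_um[1]`` are counted as overflow (logged), not binned;
    one histogram entry per tubule.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = float(range_um[0]), float(range_um[1])
    if hi <= lo:
        raise ValueError("empty histogram range")
    d = np.asarray(diameters_um, dtype=float)
    if d.size and d.min() <= 0:
        raise ValueError("diameters must be positive")
    n_bins = int(math.ceil((hi - lo) / bin_width_um))
    edges = lo + bin_width_um * np.arange(n_bins + 1)
    in_range = (d >= lo) & (d < edges[-1])
    overflow = int(np.count_nonzero(d >= edges[-1]))
    if overflow:
        logger.info("%d diameters >= %.1f um counted as overflow", overflow, edges[-1])
    idx = np.floor((d[in_range] - lo) / bin_width_um).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    return DiameterHistogram(bin_edges_um=edges, counts=counts, zone=zone, overflow=overflow)


def find_modes(hist: DiameterHistogram, min_separation_bins: int = 1) -> list[int]:
    """Indices of modal bins: strict local maxima of the count vector.

    A plateau that is a local maximum resolves to its leftmost bin.  When two
    modes are closer than ``min_separation_bins`` the one with the larger
    count wins (ties to the lower-diameter bin).  Returned sorted by count
    descending, ties broken toward the lower bin.
    """
    c = hist.counts
    n = len(c)
    if n == 0:
        return []
    candidates: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and c[j + 1] == c[i]:
            j += 1
        left_ok = i == 0 or c[i - 1] < c[i]
        right_ok = j == n - 1 or c[j + 1] < c[i]
        if left_ok and right_ok and c[i] > 0:
            candidates.append(i)  # plateau resolves left
        i = j + 1
    # enforce minimum separation: greedily keep higher-count (then lower-bin) modes
    candidates.sort(key=lambda b: (-c[b], b))
    kept: list[int] = []
    for b in candidates:
        if all(abs(b - k) >= min_separation_bins for k in kept):
            kept.append(b)
    return kept


def compare_distributions(hist_a: DiameterHistogram, hist_b: DiameterHistogram) -> float:
    """Overlap coefficient ``Σ min(p_a, p_b)`` of two normalized histograms.

    1.0 for identical distributions, 0.0 for disjoint support; requires
    identical bin edges.
    """
    if len(hist_a.bin_edges_um) != len(hist_b.bin_edges_um) or not np.allclose(
        hist_a.bin_edges_um, hist_b.bin_edges_um
    ):
        raise ValueError("histograms must share bin edges")
    return float(np.minimum(hist_a.normalized, hist_b.normalized).sum())


def plot_histogram(hists, ax=None, labels=None):
    """Basic bar plot of one or more diameter histograms (same edges)."""
    import matplotlib.pyplot as plt

    if isinstance(hists, DiameterHistogram):
        hists = [hists]
    if ax is None:
        _, ax = plt.subplots()
    width = np.diff(hists[0].bin_edges_um)
    offset = width / (len(hists) + 1)
    for k, h in enumerate(hists):
        name = labels[k] if labels else h.zone
        ax.bar(
            h.bin_edges_um[:-1] + (k + 0.5) * offset,
            h.normalized,
            width=offset,
            align="edge",
            label=name,
        )
    ax.set_xlabel("tubule diameter (μm)")
    ax.set_ylabel("fraction of tubules")
    ax.legend()
    return ax
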