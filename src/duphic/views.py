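"""Virtual 4C: one-dimensional viewpoint profiles from a contact matrix.

The profile at bin j is the summed contact of j with the viewpoint bins,
i.e. the matrix row(s) at the viewpoint — the in-silico analogue of a 4C
experiment anchored at that locus.  Profiles can be lightly smoothed and
exported as bedGraph tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import ContactMatrix
from .region import CHROM_NAME

__all__ = ["ViewpointProfile", "virtual_4c", "export_bedgraph",
           "read_bedgraph"]


@dataclass(frozen=True)
class ViewpointProfile:
    viewpoint: tuple[int, int]          # bp, half-open
    viewpoint_bins: tuple[int, ...]     # flagged, not zeroed
    bin_size: int
    values: np.ndarray                  # length n_bins, >= 0
    smooth_window: int

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def mass(self, exclude_viewpoint: bool = False) -> float:
        if not exclude_viewpoint:
            return float(self.values.sum())
        keep = np.ones(len(self.values), dtype=bool)
        keep[list(self.viewpoint_bins)] = False
        return float(self.values[keep].sum())


def virtual_4c(matrix: ContactMatrix, viewpoint: tuple[int, int],
               smooth_window: int = 3) -> ViewpointProfile:
    """Extract a viewpoint profile.

    ``viewpoint`` is a bp interval (half-open) that must overlap at
    least one bin.  The raw signal at bin j is the sum over viewpoint
    bins v of count(v, j); it is then smoothed by a centred moving
    average of odd width ``smooth_window`` whose edges are truncated
    (divide by the actual window size), so ``smooth_window=1`` is the
    identity.  Viewpoint self-bins are reported and flagged, not zeroed.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    start, end = viewpoint
    region_len = matrix.n_bins * matrix.bin_size
    if not (0 <= start < end <= region_len):
        raise ValueError("viewpoint outside the region")
    first = start // matrix.bin_size
    last = (end - 1) // matrix.bin_size
    vp_bins = tuple(range(first, last + 1))

    dense = matrix.to_dense()
    raw = dense[list(vp_bins), :].sum(axis=0)

    if smooth_window == 1:
        smoothed = raw
    else:
        kernel = np.ones(smooth_window)
        smoothed = (np.convolve(raw, kernel, mode="same")
                    / np.convolve(np.ones_like(raw), kernel, mode="same"))
    return ViewpointProfile(viewpoint=(start, end), viewpoint_bins=vp_bins,
                            bin_size=matrix.bin_size, values=smoothed,
                            smooth_window=smooth_window)


def export_bedgraph(profile: ViewpointProfile, out: str | Path,
                    name: str = "virtual4C",
                    chrom: str = CHROM_NAME) -> Path:
    """Write the profile as a 4-column bedGraph (nonzero bins only)."""
    out = Path(out)
    lines = [f'track type=bedGraph name="{name}"']
    bs = profile.bin_size
    for b, v in enumerate(profile.values):
        if v != 0:
            lines.append(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{float(v)!r}")
    out.write_text("\n".join(lines) + "\n")
    return out


def read_bedgraph(path: str | Path, n_bins: int,
                  bin_size: int) -> np.ndarray:
    """Read a bin-aligned bedGraph back to a dense per-bin array."""
    values = np.zeros(n_bins)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        _chrom, s, e, v = line.split("\t")
        s, e = int(s), int(e)
        if s % bin_size or (e - s) != bin_size:
            raise ValueError(f"interval [{s},{e}) is not bin-aligned")
        values[s // bin_size] = float(v)
    return values
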