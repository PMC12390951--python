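"""Bilateral high-density optode montage fixture.

Each hemisphere carries 10 emitters and 8 detectors on a 2-D lateral scalp
plane (x: posterior to anterior, y: inferior to superior, mm).  A channel is
any emitter-detector pair whose separation falls in the usable 15-40 mm
range; its nominal cortical location is the pair midpoint (the point of
maximal depth of the banana-shaped photon path).  The frozen coordinates
yield 39 channels on the left hemisphere and 40 on the right, and mirrored
region labels with at least three channels in each of the three analysis
ROIs (auditory, sensorimotor, premotor) per hemisphere.

The geometry is a package fixture (no photon-migration head model): region
membership is declared by midpoint zones, mirroring the functional ROI logic
of the analysis rather than anatomical reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEPARATION_RANGE_MM = (15.0, 40.0)
ANALYSIS_ROIS = ("auditory", "sensorimotor", "premotor")
REGIONS = ANALYSIS_ROIS + ("frontal", "parietal", "temporal")

# Frozen 2-D optode coordinates (mm). The left hemisphere mirrors the right
# except for one detector nudged outward so that exactly one frontal pair
# exceeds the 40 mm limit (39 vs 40 channels).
_RIGHT_EMITTERS = np.array([
    (-54.52, -16.22), (-6.64, -16.26), (28.10, -12.35), (50.07, -22.93),
    (-18.51, 2.01), (16.10, 2.36), (65.04, 2.02), (-52.33, 20.97),
    (-10.52, 18.86), (24.76, 22.15),
])
_RIGHT_DETECTORS = np.array([
    (-29.76, -12.77), (11.58, -13.09), (-37.87, 3.58), (2.48, -0.18),
    (36.64, 2.00), (-26.15, 20.61), (4.60, 17.19), (46.42, 16.83),
])
_LEFT_EMITTERS = _RIGHT_EMITTERS.copy()
_LEFT_DETECTORS = np.array([
    (-29.76, -12.77), (11.58, -13.09), (-37.87, 3.58), (2.48, -0.18),
    (36.64, 2.00), (-26.15, 20.61), (4.60, 17.19), (46.30, 18.15),
])


def _region_of(mid: np.ndarray) -> str:
    x, y = mid
    if -15 <= x <= 15 and -15 <= y <= 8:
        return "auditory"
    if -18 <= x <= 6 and y > 8:
        return "sensorimotor"
    if 6 < x <= 32 and y > 8:
        return "premotor"
    if x > 15 and y <= 8:
        return "frontal"
    if x < -15 and y <= 8:
        return "temporal"
    return "parietal"


@dataclass(frozen=True)
class Channel:
    """One emitter-detector pair."""

    index: int
    hemisphere: str  # "left" | "right"
    emitter: int
    detector: int
    midpoint_mm: tuple[float, float]
    separation_mm: float
    region: str


@dataclass
class Montage:
    """Bilateral optode layout and derived channel list."""

    emitters: dict[str, np.ndarray]
    detectors: dict[str, np.ndarray]
    channels: list[Channel] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channels_of(self, hemisphere: str | None = None, region: str | None = None) -> list[Channel]:
        out = self.channels
        if hemisphere is not None:
            out = [c for c in out if c.hemisphere == hemisphere]
        if region is not None:
            out = [c for c in out if c.region == region]
        return out

    @property
    def separations_mm(self) -> np.ndarray:
        return np.array([c.separation_mm for c in self.channels])

    @property
    def midpoints_mm(self) -> np.ndarray:
        return np.array([c.midpoint_mm for c in self.channels])

    def adjacency(self, radius_mm: float) -> np.ndarray:
        """Boolean channel adjacency: midpoints within ``radius_mm``, same
        hemisphere, excluding self-pairs."""
        mids = self.midpoints_mm
        hemi = np.array([c.hemisphere for c in self.channels])
        d = np.linalg.norm(mids[:, None, :] - mids[None, :, :], axis=-1)
        adj = (d <= radius_mm) & (hemi[:, None] == hemi[None, :])
        np.fill_diagonal(adj, False)
        return adj

    def default_neighbor_radius(self, min_neighbors: int = 2, step_mm: float = 0.5) -> float:
        """Smallest radius (on a half-mm grid) giving every channel at least
        ``min_neighbors`` within-hemisphere neighbors."""
        r = step_mm
        while r < 200:
            if self.adjacency(r).sum(axis=1).min() >= min_neighbors:
                return r
            r += step_mm
        raise RuntimeError("no radius gives the requested neighbor count")


def build_montage() -> Montage:
    """Deterministic bilateral montage fixture (39 left / 40 right channels)."""
    emitters = {"left": _LEFT_EMITTERS, "right": _RIGHT_EMITTERS}
    detectors = {"left": _LEFT_DETECTORS, "right": _RIGHT_DETECTORS}
    channels: list[Channel] = []
    lo, hi = SEPARATION_RANGE_MM
    for hemi in ("left", "right"):
        em, de = emitters[hemi], detectors[hemi]
        for i in range(em.shape[0]):
            for j in range(de.shape[0]):
                sep = float(np.linalg.norm(em[i] - de[j]))
                if lo <= sep <= hi:
                    mid = (em[i] + de[j]) / 2
                    channels.append(
                        Channel(
                            index=len(channels),
                            hemisphere=hemi,
                            emitter=i,
                            detector=j,
                            midpoint_mm=(float(mid[0]), float(mid[1])),
                            separation_mm=sep,
                            region=_region_of(mid),
                        )
                    )
    return Montage(emitters=emitters, detectors=detectors, channels=channels)
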