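"""MS2 transcription-spot detection, linking, and persistence statistics.

Nascent-transcription reporters appear as diffraction-limited bright
spots in maximum-projected time-lapse frames.  The pipeline here:

1. per-frame detection — keep pixels above an absolute intensity
   threshold, inside the embryo mask, and brighter than their local
   background by a contrast threshold, where the background is the mean
   of the one-pixel ring of an (N+2)x(N+2) window around the pixel
   (excluding the central NxN block); merge adjacent selected pixels by
   8-connectivity into spot candidates with intensity-weighted centroids;
2. frame-to-frame linking — greedy one-to-one nearest-neighbour
   assignment between consecutive frames, globally ordered by ascending
   pair distance, never linking beyond the maximum displacement, with no
   gap closing;
3. persistence filtering — tracks lasting less than a minimum duration
   (default 160 s, shorter than one complete hb transcription event) are
   discarded; a track lasting exactly the minimum is retained;
4. regional statistics — per-AP-region persistence distributions and
   spot densities.

Durations default to n_spots * frame_interval; the span convention
(n_spots - 1) * frame_interval is selectable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Anterior hb domain subdivided into five AP regions, (high, low) %EL.
ANTERIOR_REGIONS = ((100.0, 75.0), (75.0, 70.0), (70.0, 65.0),
                    (65.0, 60.0), (60.0, 40.0))
POSTERIOR_REGION = (40.0, 0.0)


@dataclass(frozen=True)
class APAxisCalibration:
    """Linear map from pixel column to %EL (anterior = 100 %EL)."""

    el_at_x0: float            # %EL of pixel column 0
    el_per_px: float           # signed %EL per pixel

    def __post_init__(self):
        if self.el_per_px == 0:
            raise InvalidInputError("calibration must be monotone (el_per_px != 0)")

    def el(self, x_px):
        return self.el_at_x0 + self.el_per_px * np.asarray(x_px, dtype=float)

    def px(self, el):
        return (np.asarray(el, dtype=float) - self.el_at_x0) / self.el_per_px


@dataclass
class MovieStack:
    """Maximum-projected time-lapse frames with acquisition metadata."""

    frames: np.ndarray            # (n_frames, height, width)
    frame_interval_s: float = 40.0
    pixel_size_nm: float = 510.0
    ap_axis: APAxisCalibration = field(
        default_factory=lambda: APAxisCalibration(el_at_x0=100.0, el_per_px=-0.1)
    )

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidInputError("frames must be (time, height, width)")
        if self.frame_interval_s <= 0:
            raise InvalidInputError("frame_interval_s must be positive")
        if np.any(self.frames < 0):
            raise InvalidInputError("intensities must be non-negative")


@dataclass(frozen=True)
class TrackingConfig:
    """Manually measured tracking parameters.

    intensity_threshold   lowest intensity value counted as signal
    spot_size_n           odd N of the NxN spot matrix
    max_displacement_px   maximum spot displacement between two frames
    contrast_threshold    required intensity difference between an MS2
                          dot and its surrounding background
    min_duration_s        persistence cut-off; shorter tracks are dropped
    duration_convention   'count' (n * dt, default) or 'span' ((n-1) * dt)
    """

    intensity_threshold: float = 100.0
    spot_size_n: int = 3
    max_displacement_px: float = 5.0
    contrast_threshold: float = 50.0
    min_duration_s: float = 160.0
    duration_convention: str = "count"

    def __post_init__(self):
        if self.spot_size_n < 1 or self.spot_size_n % 2 == 0:
            raise InvalidInputError("spot_size_n must be odd and >= 1")
        for name in ("intensity_threshold", "max_displacement_px",
                     "contrast_threshold", "min_duration_s"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.duration_convention not in ("count", "span"):
            raise InvalidInputError("duration_convention must be 'count' or 'span'")


@dataclass
class SpotCandidate:
    frame_index: int
    x: float                    # intensity-weighted centroid, px
    y: float
    mean_intensity: float
    ap_position: float          # %EL

    @property
    def centroid_yx(self):
        return (self.y, self.x)


@dataclass
class Track:
    """A linked run of spot detections in strictly consecutive frames."""

    spots: list
    frame_interval_s: float = 40.0
    duration_convention: str = "count"
    region: str | None = None

    def __post_init__(self):
        frames = [s.frame_index for s in self.spots]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise InvalidInputError("track spots must occupy consecutive frames")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def duration_s(self) -> float:
        n = self.n_spots
        if self.duration_convention == "span":
            n = n - 1
        return n * self.frame_interval_s

    @property
    def mean_ap(self) -> float:
        return float(np.mean([s.ap_position for s in self.spots]))


def residual_signal_window_min(reporter_length_kb: float = 6.4,
                               elongation_rate_kb_per_min: float = 1.54) -> int:
    """Whole minutes for polymerase to traverse the reporter gene.

    After transcription initiation stops, already-loaded polymerases keep
    elongating, so reporter fluorescence persists for the traversal time
    of the construct — truncated to whole minutes, the window of residual
    signal expected after an instantaneous shutdown.
    """
    if reporter_length_kb <= 0 or elongation_rate_kb_per_min <= 0:
        raise InvalidInputError("length and rate must be positive")
    return int(reporter_length_kb / elongation_rate_kb_per_min)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def embryo_mask(frame: np.ndarray, min_area_fraction: float = 0.05
                ) -> np.ndarray:
    """Binary embryo mask: filled largest connected bright region.

    If the largest bright region covers less than ``min_area_fraction``
    of the frame the field of view is taken to lie entirely inside the
    embryo (common for cropped or synthetic movies) and an all-true mask
    is returned.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.max() == frame.min():
        return np.ones(frame.shape, dtype=bool)
    bright = frame > threshold_otsu(frame)
    labels = cc_label(bright, connectivity=2)
    if labels.max() == 0:
        return np.ones(frame.shape, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    if mask.sum() < min_area_fraction * mask.size:
        return np.ones(frame.shape, dtype=bool)
    return mask


def _contrast_image(frame: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel minus ring-background, and validity mask for interior pixels.

    The background of a pixel is the mean over the one-pixel ring of the
    (n+2)x(n+2) window centred on it, i.e. the window minus its central
    nxn block.  Pixels whose (n+2)-window would leave the frame are
    invalid (skipped by the caller).
    """
    m = n + 2
    frame = np.asarray(frame, dtype=float)
    sum_outer = ndimage.uniform_filter(frame, size=m, mode="constant") * (m * m)
    sum_inner = ndimage.uniform_filter(frame, size=n, mode="constant") * (n * n)
    ring_mean = (sum_outer - sum_inner) / (m * m - n * n)
    contrast = frame - ring_mean
    valid = np.zeros(frame.shape, dtype=bool)
    half = m // 2
    if frame.shape[0] > 2 * half and frame.shape[1] > 2 * half:
        valid[half:frame.shape[0] - half, half:frame.shape[1] - half] = True
    return contrast, valid


def select_pixels(frame: np.ndarray, config: TrackingConfig,
                  mask: np.ndarray) -> np.ndarray:
    """Boolean image of pixels passing threshold, mask, and contrast tests."""
    frame = np.asarray(frame, dtype=float)
    if mask.shape != frame.shape:
        raise InvalidInputError("mask shape does not match frame")
    contrast, valid = _contrast_image(frame, config.spot_size_n)
    above = frame >= config.intensity_threshold
    n_border_skipped = int(np.count_nonzero(above & mask & ~valid))
    if n_border_skipped:
        logger.info("skipped %d candidate pixels at the frame border",
                    n_border_skipped)
    return above & mask & valid & (contrast >= config.contrast_threshold)


def detect_spots(stack: MovieStack, config: TrackingConfig,
                 mask: np.ndarray | None = None) -> list:
    """Detect spot candidates in every frame of a projected movie.

    ``mask`` is the embryo-boundary mask shared by all frames; when
    omitted it is derived from the maximum projection over time.
    Returns one list of :class:`SpotCandidate` per frame.
    """
    if mask is None:
        mask = embryo_mask(stack.frames.max(axis=0))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frames.shape[1:]:
        raise InvalidInputError("mask shape does not match frames")
    per_frame: list = []
    for t, frame in enumerate(stack.frames):
        selected = select_pixels(frame, config, mask)
        labels = cc_label(selected, connectivity=2)
        spots = []
        frame_f = np.asarray(frame, dtype=float)
        for lbl in range(1, labels.max() + 1):
            ys, xs = np.nonzero(labels == lbl)
            weights = frame_f[ys, xs]
            total = weights.sum()
            cx = float((xs * weights).sum() / total)
            cy = float((ys * weights).sum() / total)
            spots.append(SpotCandidate(
                frame_index=t, x=cx, y=cy,
                mean_intensity=float(weights.mean()),
                ap_position=float(stack.ap_axis.el(cx)),
            ))
        per_frame.append(spots)
    return per_frame


# ---------------------------------------------------------------------------
# linking and filtering
# ---------------------------------------------------------------------------


def link_tracks(spots_by_frame: list, config: TrackingConfig,
                frame_interval_s: float = 40.0) -> list:
    """Greedy one-to-one nearest-neighbour linking of consecutive frames.

    Candidate pairs within the displacement range are linked in order of
    ascending distance, ties broken by the smaller (y, x) centroid of the
    earlier then the later spot; each spot links at most once per frame
    pair.  Unlinked spots start new tracks.  No gap closing.
    """
    active: dict = {}            # spot object id in latest frame -> spot list
    finished: list = []
    prev_spots: list = []
    for spots in spots_by_frame:
        pairs = []
        for i, a in enumerate(prev_spots):
            for j, b in enumerate(spots):
                d = float(np.hypot(a.x - b.x, a.y - b.y))
                if d <= config.max_displacement_px:
                    pairs.append((d, a.centroid_yx, b.centroid_yx, i, j))
        pairs.sort()
        used_prev: set = set()
        used_next: set = set()
        links: dict = {}
        for d, _, _, i, j in pairs:
            if i in used_prev or j in used_next:
                continue
            used_prev.add(i)
            used_next.add(j)
            links[j] = i
        next_active: dict = {}
        for j, spot in enumerate(spots):
            if j in links:
                run = active.pop(id(prev_spots[links[j]]))
                run.append(spot)
            else:
                run = [spot]
            next_active[id(spot)] = run
        finished.extend(active.values())   # runs not extended end here
        active = next_active
        prev_spots = spots
    finished.extend(active.values())
    return [Track(spots=run, frame_interval_s=frame_interval_s,
                  duration_convention=config.duration_convention)
            for run in finished]


def filter_tracks(tracks: list, config: TrackingConfig) -> list:
    """Drop tracks shorter than the persistence cut-off.

    A track lasting exactly ``min_duration_s`` is retained (only strictly
    shorter tracks are excluded).  Idempotent.
    """
    return [t for t in tracks if t.duration_s >= config.min_duration_s]


# ---------------------------------------------------------------------------
# regional statistics
# ---------------------------------------------------------------------------


@dataclass
class RegionStats:
    region: str
    n_tracks: int
    mean_min: float              # NaN when empty
    sd_min: float
    hist_durations_min: np.ndarray   # distinct durations, minutes
    hist_probs: np.ndarray           # sums to 1 when non-empty


def _region_label(high: float, low: float) -> str:
    def fmt(v):
        return f"{v:g}"
    return f"{fmt(high)}-{fmt(low)}"


def persistence_stats(tracks: list, regions=ANTERIOR_REGIONS) -> dict:
    """Per-AP-region persistence distributions, in minutes.

    Each track is assigned to the region containing its mean AP position;
    a region labelled "high-low" covers the half-open interval
    (low, high], so a track sitting exactly on a shared edge belongs to
    the more anterior-labelled region below it (75 %EL falls in "75-70").
    Tracks outside every region land in an ``unassigned`` bucket with a
    warning.
    """
    buckets: dict = {_region_label(h, l): [] for h, l in regions}
    unassigned = []
    for track in tracks:
        ap = track.mean_ap
        placed = False
        for high, low in regions:
            if low < ap <= high:
                buckets[_region_label(high, low)].append(track)
                track.region = _region_label(high, low)
                placed = True
                break
        if not placed:
            unassigned.append(track)
            track.region = "unassigned"
    if unassigned:
        warnings.warn(f"{len(unassigned)} tracks outside all regions",
                      stacklevel=2)
        buckets["unassigned"] = unassigned
    out: dict = {}
    for region, members in buckets.items():
        durations_min = np.array([t.duration_s / 60.0 for t in members])
        if len(durations_min):
            vals, counts = np.unique(durations_min, return_counts=True)
            probs = counts / counts.sum()
            mean = float(durations_min.mean())
            sd = float(durations_min.std(ddof=1)) if len(durations_min) > 1 else 0.0
        else:
            vals = np.array([])
            probs = np.array([])
            mean = sd = float("nan")
        out[region] = RegionStats(region=region, n_tracks=len(members),
                                  mean_min=mean, sd_min=sd,
                                  hist_durations_min=vals, hist_probs=probs)
    return out


def spot_density(spots_by_frame: list, domain: tuple,
                 ap_axis: APAxisCalibration, height_px: int) -> np.ndarray:
    """Spots per 100x100 px^2 of an AP domain, per frame.

    ``domain`` is a (high, low) %EL interval; its pixel area is the
    domain width in pixels (through the AP calibration) times the frame
    height.
    """
    hi, lo = max(domain), min(domain)
    x_edges = ap_axis.px([hi, lo])
    width_px = abs(float(x_edges[1] - x_edges[0]))
    area = width_px * height_px
    if area <= 0:
        raise InvalidInputError("domain has zero pixel area")
    unit_areas = area / 1.0e4      # 100x100 px^2 units
    counts = np.array([
        sum(1 for s in spots if lo <= s.ap_position <= hi)
        for spots in spots_by_frame
    ], dtype=float)
    return counts / unit_areas
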