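"""Seeded synthetic-data generators and the reference gene-circuit fixture.

Everything here is generator-side: it produces inputs with the
statistical structure the analysis modules assume (exponential Bcd-like
gradients with an ~80 µm decay length, MS2 spot movies with known track
durations, gap-gene-like profiles with boundaries at stated positions)
together with the ground truth needed for recovery tests.  All
randomness flows through a single integer seed; identical (config, seed)
pairs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import (GENES, MATERNAL_INPUTS, AxisGrid, CircuitParams,
                      MaternalField)
from .errors import InvalidInputError
from .ms2 import APAxisCalibration, MovieStack
from .profiles import NuclearRecord

# ---------------------------------------------------------------------------
# maternal inputs
# ---------------------------------------------------------------------------

#: Shape constants of the maternal profiles (positions in %EL).
CAD_MIDPOINT, CAD_SLOPE = 41.5, 4.0
TLL_MIDPOINT, TLL_SLOPE = 31.73, 4.0
HKB_ANT_MIDPOINT, HKB_ANT_SLOPE = 85.0, 3.0
HKB_POLE_WIDTH = 8.0


def make_maternal_inputs(grid: AxisGrid, length_scale_um: float = 80.0,
                         seed: int | None = None) -> MaternalField:
    """Canonical maternal-input profiles on a grid, all scaled to [0, 1].

    Bcd is an exponential gradient from the anterior pole with the given
    decay length in microns; Cad is a posterior logistic ramp; Tll a
    posterior terminal domain; Hkb an anterior terminal domain plus a
    narrow posterior pole bump.  The profiles are deterministic (``seed``
    is accepted for interface symmetry with the stochastic generators).
    """
    if length_scale_um <= 0:
        raise InvalidInputError("length_scale_um must be positive")
    x = grid.positions
    d_um = grid.microns_from_anterior()
    bcd = np.exp(-d_um / length_scale_um)
    cad = 1.0 / (1.0 + np.exp((x - CAD_MIDPOINT) / CAD_SLOPE))
    tll = 1.0 / (1.0 + np.exp((x - TLL_MIDPOINT) / TLL_SLOPE))
    hkb = (1.0 / (1.0 + np.exp((HKB_ANT_MIDPOINT - x) / HKB_ANT_SLOPE))
           + np.exp(-(x / HKB_POLE_WIDTH) ** 2))
    profiles = {"bcd": bcd, "cad": cad, "tll": tll,
                "hkb": np.clip(hkb, 0.0, 1.0)}
    return MaternalField(grid=grid, profiles=profiles)


# ---------------------------------------------------------------------------
# reference circuit fixture
# ---------------------------------------------------------------------------


def make_reference_circuit(seed: int | None = None) -> CircuitParams:
    """The shipped, version-pinned reference parameter set.

    Hand-tuned so that a dark-control simulation with the default
    maternal inputs yields the wild-type-like pattern: an anterior Hb
    domain, anterior Gt expression, a central Kr band with half-maximum
    boundaries at 58 and 45 %EL, and a posterior Kni domain spanning
    45-37 %EL.  Deterministic; ``seed`` is ignored.

    Every expression boundary is a forced front read off smooth input
    profiles (Bcd, Cad, Tll, Hkb thresholds plus Hb-dimer repression for
    the Kr anterior edge), so end-state patterns converge under grid
    refinement and respond monotonically to Bcd shutdown.  The Bcd
    column on kni is net-repressive, standing in for Bcd-activated
    anterior repressors that are not explicit circuit species; gap-gene
    cross-repression is kept minimal for the same reason.
    """
    # gene order: hb, gt, kr, kni
    # regulators: hb_m, hb_d, gt, kr, kni
    T = np.array([
        #  hb_m   hb_d    gt     kr    kni
        [  0.0,   0.0,   0.0,    0.0, -10.0],   # hb
        [  0.0,   0.0,   0.0,    0.0,   0.0],   # gt
        [  0.0,  -90.0,  0.0,    0.0,   0.0],   # kr
        [  0.0,  -60.0,  0.0,    0.0,   0.0],   # kni
    ])
    # maternal inputs: bcd, cad, tll, hkb
    M = np.array([
        [ 225.0,   0.0,    0.0,    0.0],        # hb
        [ 150.0,   0.0,  -40.0,  -40.0],        # gt
        [  90.0, -40.0,  -60.0, -150.0],        # kr
        [-200.0,  40.0, -120.0,    0.0],        # kni
    ])
    h = np.array([-15.93, -16.8, 10.84, -1.48])
    R = np.array([0.08, 0.08, 0.08, 0.08])
    lam = np.array([0.08, 0.08, 0.08, 0.08])
    D = np.array([0.2, 0.2, 0.2, 0.2])
    return CircuitParams(T=T, M=M, h=h, R=R, lam=lam, D=D, K_hb=0.25,
                         params_id="reference")


def reference_initial_state(grid: AxisGrid) -> np.ndarray:
    """Initial concentrations: maternal-Hb-like anterior step, others zero."""
    v0 = np.zeros((len(GENES), grid.n_bins))
    x = grid.positions
    v0[GENES.index("hb")] = 0.6 / (1.0 + np.exp((55.0 - x) / 4.0))
    return v0


def make_param_ensemble(reference: CircuitParams, n: int = 21,
                        jitter: float = 0.15,
                        seed: int | None = 0) -> list[CircuitParams]:
    """Sign-preserving lognormal jitter around a reference parameter set.

    Member 0 is the reference unchanged; members 1..n-1 multiply every
    nonzero scalar parameter by exp(N(0, jitter)).  Zero entries (absent
    interactions) stay zero so the network topology is shared.
    """
    if n < 1:
        raise InvalidInputError("ensemble size must be >= 1")
    if jitter < 0:
        raise InvalidInputError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    out = [CircuitParams.from_dict({**reference.to_dict(), "params_id": "set00"})]
    for k in range(1, n):
        d = reference.to_dict()
        for key in ("T", "M", "h", "R", "lam", "D"):
            arr = np.array(d[key], dtype=float)
            factors = np.exp(rng.normal(0.0, jitter, size=arr.shape))
            d[key] = (arr * np.where(arr != 0, factors, 1.0)).tolist()
        d["K_hb"] = float(d["K_hb"] * np.exp(rng.normal(0.0, jitter)))
        d["params_id"] = f"set{k:02d}"
        out.append(CircuitParams.from_dict(d))
    return out


# ---------------------------------------------------------------------------
# MS2 movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthMovieConfig:
    """Geometry, kinetics, and noise of a synthetic MS2 movie.

    Spot on-durations are drawn per nucleus from a truncated normal
    (floor 0) with the given mean and sd in minutes; defaults follow the
    control-embryo persistence statistics (7.1 +/- 3.2 min) and a 40 s
    frame interval.  Frames are desk-scale 256x128 px with the field of
    view mapped linearly onto 100-40 %EL.
    """

    width: int = 256
    height: int = 128
    n_frames: int = 24
    frame_interval_s: float = 40.0
    n_nuclei: int = 12
    spot_probability: float = 0.85
    persistence_mean_min: float = 7.1
    persistence_sd_min: float = 3.2
    spot_amplitude: float = 800.0
    spot_sigma_px: float = 1.2
    noise_sd: float = 10.0
    poisson_noise: bool = False
    drift_px_per_frame: float = 0.3
    min_separation_px: float = 16.0
    ap_el_range: tuple = (100.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height, self.n_frames, self.n_nuclei) <= 0:
            raise InvalidInputError("dimensions must be positive")
        if self.persistence_mean_min <= 0:
            raise InvalidInputError("persistence mean must be positive")
        if not (0.0 <= self.spot_probability <= 1.0):
            raise InvalidInputError("spot_probability must be in [0, 1]")

    @property
    def calibration(self) -> APAxisCalibration:
        hi, lo = self.ap_el_range
        return APAxisCalibration(el_at_x0=hi, el_per_px=(lo - hi) / self.width)


@dataclass
class TrueTrack:
    """Generator-side truth for one rendered spot run."""

    nucleus_id: int
    start_frame: int
    end_frame: int               # inclusive
    positions: np.ndarray        # (n_on, 2) of (x, y) px per frame
    ap_positions: np.ndarray

    @property
    def n_frames_on(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, frame_interval_s: float,
                   convention: str = "count") -> float:
        n = self.n_frames_on
        if convention == "span":
            n -= 1
        return n * frame_interval_s


@dataclass
class SynthGroundTruth:
    """Truth emitted alongside synthetic data, for recovery tests."""

    tracks: list = field(default_factory=list)
    gradient_params: dict | None = None
    boundaries: dict | None = None
    crowded: bool = False        # nucleus placement hit the density limit


def _truncated_normal(rng, mean: float, sd: float, floor: float = 0.0) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return floor + mean          # pathological parameters; keep going


def _place_nuclei(rng, config: SynthMovieConfig) -> tuple[np.ndarray, bool]:
    margin = 8.0
    pts: list = []
    crowded = False
    for _ in range(config.n_nuclei):
        ok = False
        for _ in range(2000):
            p = np.array([rng.uniform(margin, config.width - margin),
                          rng.uniform(margin, config.height - margin)])
            if all(np.hypot(*(p - q)) >= config.min_separation_px for q in pts):
                pts.append(p)
                ok = True
                break
        if not ok:
            crowded = True
            pts.append(np.array([rng.uniform(margin, config.width - margin),
                                 rng.uniform(margin, config.height - margin)]))
    return np.array(pts), crowded


def render_noiseless(truth: SynthGroundTruth,
                     config: SynthMovieConfig) -> np.ndarray:
    """Deterministically re-render frames from ground-truth tracks."""
    frames = np.zeros((config.n_frames, config.height, config.width))
    yy, xx = np.mgrid[0:config.height, 0:config.width]
    s2 = 2.0 * config.spot_sigma_px ** 2
    for track in truth.tracks:
        for k, frame_idx in enumerate(range(track.start_frame,
                                            track.end_frame + 1)):
            x, y = track.positions[k]
            frames[frame_idx] += config.spot_amplitude * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / s2)
    return frames


def make_ms2_movie(config: SynthMovieConfig) -> tuple[MovieStack, SynthGroundTruth]:
    """Render a synthetic MS2 movie plus its ground truth.

    Each nucleus turns on with probability ``spot_probability`` for a
    truncated-normal duration; the on-interval is placed uniformly so it
    fits inside the movie, and the spot drifts at a fixed per-nucleus
    heading.  Noise (additive Gaussian, optionally Poisson) is applied
    after rendering and clipped at zero.
    """
    rng = np.random.default_rng(config.seed)
    centres, crowded = _place_nuclei(rng, config)
    cal = config.calibration
    tracks: list = []
    for nid, centre in enumerate(centres):
        if rng.uniform() > config.spot_probability:
            continue
        dur_min = _truncated_normal(rng, config.persistence_mean_min,
                                    config.persistence_sd_min)
        n_on = int(np.clip(round(dur_min * 60.0 / config.frame_interval_s),
                           1, config.n_frames))
        start = int(rng.integers(0, config.n_frames - n_on + 1))
        heading = rng.uniform(0.0, 2.0 * np.pi)
        step = config.drift_px_per_frame * np.array([np.cos(heading),
                                                     np.sin(heading)])
        positions = centre[None, :] + np.arange(n_on)[:, None] * step
        tracks.append(TrueTrack(
            nucleus_id=nid, start_frame=start, end_frame=start + n_on - 1,
            positions=positions,
            ap_positions=cal.el(positions[:, 0]),
        ))
    truth = SynthGroundTruth(tracks=tracks, crowded=crowded)
    frames = render_noiseless(truth, config)
    if config.noise_sd > 0:
        frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
    if config.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    frames = np.clip(frames, 0.0, None)
    stack = MovieStack(frames=frames, frame_interval_s=config.frame_interval_s,
                       ap_axis=cal)
    return stack, truth


# ---------------------------------------------------------------------------
# gradient nuclei
# ---------------------------------------------------------------------------


def make_gradient_nuclei(n_nuclei: int = 500,
                         true_params: dict | None = None,
                         noise_sd: float = 0.05,
                         seed: int = 0,
                         embryo_length: float = 500.0
                         ) -> tuple[list[NuclearRecord], SynthGroundTruth]:
    """Nuclei sampling an exponential AP gradient with multiplicative noise.

    ``true_params`` holds amplitude, length_scale (µm) and offset of the
    generating model; intensities are model * (1 + N(0, noise_sd)).
    Nuclei are uniform along the AP axis.
    """
    params = {"amplitude": 1000.0, "length_scale": 80.0, "offset": 0.0}
    if true_params:
        params.update(true_params)
    if params["length_scale"] <= 0:
        raise InvalidInputError("true length_scale must be positive")
    rng = np.random.default_rng(seed)
    pos_um = rng.uniform(0.0, embryo_length, size=n_nuclei)
    d_anterior = embryo_length - pos_um
    model = (params["amplitude"] * np.exp(-d_anterior / params["length_scale"])
             + params["offset"])
    intensity = model * (1.0 + rng.normal(0.0, noise_sd, size=n_nuclei))
    nuclei = [
        NuclearRecord(embryo_id="synthetic",
                      position_um=float(p),
                      percent_el=float(p / embryo_length * 100.0),
                      mean_intensity=float(i))
        for p, i in zip(pos_um, intensity)
    ]
    truth = SynthGroundTruth(gradient_params=params)
    return nuclei, truth
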