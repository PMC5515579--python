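"""AP expression-profile quantification.

Nuclear intensities are binned along the anterior–posterior axis,
morphogen gradients are fitted to an exponential with a decay length in
microns, and expression-domain boundaries are called at half of the
domain peak with linear interpolation between bins.  Positions are %EL
with the anterior pole at 100.  A thin ChIP-qPCR percent-input utility
completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainNotFoundError, FitFailureError, InvalidInputError

#: Default half-maximum boundary search windows per gene, %EL (low, high).
#: The central Krüppel band sits at 58-45 %EL and the posterior knirps
#: domain at 45-37 %EL in the wild type; windows are deliberately wider so
#: shifted boundaries remain in view.
DEFAULT_DOMAINS = {
    "hb_anterior": (35.0, 100.0),
    "gt_anterior": (55.0, 100.0),
    "kr": (25.0, 95.0),
    "kni_posterior": (20.0, 60.0),
    "kni_anterior": (80.0, 100.0),
}


@dataclass
class NuclearRecord:
    """One segmented nucleus: position along the AP axis plus intensity."""

    embryo_id: str
    position_um: float       # distance from the posterior pole, µm
    percent_el: float
    mean_intensity: float

    def __post_init__(self):
        if not (0.0 <= self.percent_el <= 100.0):
            raise InvalidInputError("percent_el must lie in [0, 100]")
        if not np.isfinite(self.mean_intensity):
            raise InvalidInputError("mean_intensity must be finite")


@dataclass
class ExpressionProfile:
    """Intensity versus AP position; the common currency of boundary calls.

    ``values`` may contain NaN for empty bins.  ``normalization`` records
    which convention produced the stored values.
    """

    positions: np.ndarray    # %EL, strictly increasing
    values: np.ndarray
    normalization: str = "none"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise InvalidInputError("positions and values must match in length")
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidInputError("positions must be strictly increasing")

    def normalized(self, mode: str = "peak",
                   posterior_window: tuple = (0.0, 55.0)) -> "ExpressionProfile":
        """Rescale so the (posterior-domain) peak equals 1.

        ``mode='peak'`` divides by the global maximum; ``'posterior_peak'``
        divides by the maximum inside ``posterior_window`` — the convention
        used for Hb, whose posterior domain serves as the internal
        intensity standard.  Normalising an already-normalised profile is
        a no-op.
        """
        if self.normalization == mode:
            return self
        if mode == "peak":
            ref = np.nanmax(self.values)
        elif mode == "posterior_peak":
            sel = (self.positions >= posterior_window[0]) & \
                  (self.positions <= posterior_window[1])
            if not sel.any():
                raise InvalidInputError("posterior window contains no bins")
            ref = np.nanmax(self.values[sel])
        else:
            raise InvalidInputError(f"unknown normalization mode '{mode}'")
        if not np.isfinite(ref) or ref <= 0:
            raise InvalidInputError("profile peak must be positive to normalize")
        return ExpressionProfile(self.positions, self.values / ref,
                                 normalization=mode)


@dataclass
class ExpFitResult:
    """Exponential gradient fit: amplitude * exp(-d / length_scale) + offset."""

    amplitude: float
    length_scale: float      # µm
    offset: float
    rms_residual: float

    def __post_init__(self):
        if self.length_scale <= 0:
            raise InvalidInputError("length_scale must be positive")
        if self.rms_residual < 0:
            raise InvalidInputError("rms_residual must be non-negative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_profile(nuclei: list, bin_width_um: float = 5.0,
                    embryo_length: float = 500.0,
                    background: float = 0.0) -> ExpressionProfile:
    """Bin nuclei into spatial steps along the AP axis and average.

    Nuclei whose distance-from-posterior falls in [k*w, (k+1)*w) share bin
    k; the bin value is the mean background-subtracted intensity.  Bins
    with no nuclei are NaN (missing), not zero.
    """
    if not nuclei:
        raise InvalidInputError("need at least one nucleus")
    n_bins = int(np.ceil(embryo_length / bin_width_um))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for nuc in nuclei:
        k = int(nuc.position_um // bin_width_um)
        if 0 <= k < n_bins:
            sums[k] += nuc.mean_intensity - background
            counts[k] += 1
    values = np.full(n_bins, np.nan)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    centres_um = (np.arange(n_bins) + 0.5) * bin_width_um
    positions = centres_um / embryo_length * 100.0
    return ExpressionProfile(positions=positions, values=values)


def subtract_background_opening(image, size: int = 25):
    """Background-subtract an intensity image by grayscale opening.

    The opening with a ``size``-pixel square structuring element estimates
    the smooth background (anything narrower than the element is removed);
    subtracting it flattens illumination before nuclear intensities are
    measured.  ``size`` should comfortably exceed a nuclear diameter.
    """
    from scipy.ndimage import grey_opening

    if size < 1:
        raise InvalidInputError("structuring size must be >= 1")
    image = np.asarray(image, dtype=float)
    return image - grey_opening(image, size=(size, size))


def profile_from_nuclei(nuclei: list) -> ExpressionProfile:
    """Unbinned profile: one point per nucleus, sorted by AP position.

    Bypasses spatial averaging for fits where per-nucleus resolution is
    wanted; duplicate positions are averaged to keep positions strictly
    increasing.
    """
    if not nuclei:
        raise InvalidInputError("need at least one nucleus")
    pos = np.array([n.percent_el for n in nuclei])
    val = np.array([n.mean_intensity for n in nuclei])
    order = np.argsort(pos)
    pos, val = pos[order], val[order]
    uniq, inverse = np.unique(pos, return_inverse=True)
    sums = np.bincount(inverse, weights=val)
    counts = np.bincount(inverse)
    return ExpressionProfile(positions=uniq, values=sums / counts)


def fit_exponential(profile: ExpressionProfile, embryo_length: float = 500.0,
                    with_offset: bool = True) -> ExpFitResult:
    """Least-squares exponential fit of a gradient profile.

    The model is value(x) = A * exp(-d(x) / l) + c with d(x) the distance
    from the anterior pole in µm.  Initialisation is deterministic
    (A = max - min, c = min, l = embryo_length / 6) so repeated fits are
    bit-identical.
    """
    sel = np.isfinite(profile.values)
    d = (100.0 - profile.positions[sel]) / 100.0 * embryo_length
    y = profile.values[sel]
    if len(y) < (3 if with_offset else 2):
        raise InvalidInputError("too few finite bins to fit")
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitFailureError("constant profile: length scale unidentifiable")
    p0 = [span, embryo_length / 6.0]
    if with_offset:
        p0.append(float(y.min()))

    def model(dd, A, l, c=0.0):
        return A * np.exp(-dd / l) + c

    try:
        popt, _ = curve_fit(model, d, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"exponential fit did not converge: {exc}",
                              last_iterate=p0) from exc
    A, l = popt[0], popt[1]
    c = popt[2] if with_offset else 0.0
    if l <= 0:
        raise FitFailureError("fit converged to non-positive length scale",
                              last_iterate=popt)
    resid = y - model(d, *popt)
    return ExpFitResult(amplitude=float(A), length_scale=float(l),
                        offset=float(c),
                        rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def boundary_position(profile: ExpressionProfile, side: str,
                      domain: tuple = (0.0, 100.0)) -> float:
    """Half-maximum boundary of an expression domain, in %EL.

    The peak is the maximum of the profile restricted to ``domain``; the
    boundary is where the profile crosses peak/2 on the requested flank,
    linearly interpolated between bins.  ``side='anterior'`` returns the
    crossing anterior of the peak (nearer 100 %EL), ``'posterior'`` the
    crossing posterior of it.
    """
    if side not in ("anterior", "posterior"):
        raise InvalidInputError("side must be 'anterior' or 'posterior'")
    lo, hi = min(domain), max(domain)
    sel = (profile.positions >= lo) & (profile.positions <= hi) & \
          np.isfinite(profile.values)
    pos = profile.positions[sel]
    val = profile.values[sel]
    if len(pos) < 2:
        raise DomainNotFoundError("domain window contains fewer than two bins")
    peak = val.max()
    if peak <= 0:
        raise DomainNotFoundError("no positive expression in domain window")
    half = peak / 2.0
    i_peak = int(np.argmax(val))
    if side == "anterior":
        idx = range(i_peak, len(pos) - 1)          # walk toward 100 %EL
    else:
        idx = range(i_peak - 1, -1, -1)            # walk toward 0 %EL
    for i in idx:
        a, b = val[i], val[i + 1]
        if (a - half) * (b - half) <= 0 and a != b:
            frac = (half - a) / (b - a)
            return float(pos[i] + frac * (pos[i + 1] - pos[i]))
    raise DomainNotFoundError(
        f"no half-maximum crossing on the {side} flank within {domain}"
    )


def percent_input(ct_ip: float, adjusted_input: float) -> float:
    """ChIP-qPCR percent-input: 100 * 2^(adjusted input - Ct(IP)).

    ``adjusted_input`` is the input-control Ct corrected for the input
    fraction: Ct(input) - log2(100 / input_percent), conventionally with a
    2 % input aliquot.
    """
    if not (np.isfinite(ct_ip) and np.isfinite(adjusted_input)):
        raise InvalidInputError("Ct values must be finite")
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def adjust_input_ct(ct_input: float, input_fraction_percent: float = 2.0) -> float:
    """Dilution-corrected input Ct: Ct(input) - log2(100 / fraction%)."""
    if input_fraction_percent <= 0:
        raise InvalidInputError("input fraction must be positive")
    return ct_input - np.log2(100.0 / input_fraction_percent)


def relative_percent_input(light: float, dark: float) -> float:
    """Percent input of illuminated embryos relative to the dark control."""
    if dark == 0:
        raise InvalidInputError("dark percent input must be nonzero")
    return light / dark
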