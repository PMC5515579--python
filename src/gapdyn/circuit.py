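"""Gap-gene circuit model on a 1-D anterior–posterior axis.

The four trunk gap genes (hunchback, giant, Krüppel, knirps) are modelled
as coupled reaction–diffusion equations on a discretised AP axis.  Each
gene ``a`` evolves as

    dv_a/dt = R_a * Phi(u_a(x, t)) - lam_a * v_a + D_a * d2v_a/dx2

with no-flux boundaries, where the regulatory input ``u_a`` is a weighted
sum of gap-gene products (Hb split into monomeric and dimeric forms) and
maternal inputs (Bcd, Cad, Tll, Hkb) plus a basal offset.  Positions are
percent egg length (%EL) with the anterior pole at 100 %EL and the
posterior pole at 0 %EL; time is minutes on a clock anchored at the onset
of gastrulation (t = 0), so simulations run over negative times.

Optogenetic shutdown of Bicoid-dependent transcription is modelled by
zeroing the entire Bcd column of the maternal-input weight matrix during
the illuminated intervals of a scenario; the switch is instantaneous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError, NumericalFailureError
from .timeline import IlluminationScenario

GENES = ("hb", "gt", "kr", "kni")
REGULATORS = ("hb_m", "hb_d", "gt", "kr", "kni")
MATERNAL_INPUTS = ("bcd", "cad", "tll", "hkb")

BCD_INDEX = MATERNAL_INPUTS.index("bcd")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxisGrid:
    """Discretisation of the AP axis in %EL.

    Bin 0 abuts the posterior pole (0 %EL); the last bin abuts the
    anterior pole (100 %EL).  ``embryo_length`` converts %EL to microns.
    The 0.5 %EL default bin width resolves every expression front of the
    reference fixture by several bins.
    """

    n_bins: int = 200
    bin_width: float = 0.5
    embryo_length: float = 500.0

    def __post_init__(self):
        if self.n_bins < 10:
            raise InvalidInputError(f"n_bins must be >= 10, got {self.n_bins}")
        if not np.isclose(self.n_bins * self.bin_width, 100.0):
            raise InvalidInputError(
                f"n_bins * bin_width must equal 100 %EL, got "
                f"{self.n_bins * self.bin_width}"
            )
        if self.embryo_length <= 0:
            raise InvalidInputError("embryo_length must be positive")

    @property
    def positions(self) -> np.ndarray:
        """Bin centres in %EL, ascending from posterior to anterior."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def microns_from_anterior(self) -> np.ndarray:
        """Distance of each bin centre from the anterior pole, in µm."""
        return (100.0 - self.positions) / 100.0 * self.embryo_length


@dataclass
class CircuitParams:
    """Interaction weights and kinetic constants of the gap-gene circuit.

    T          (4, 5) weights of regulators (hb_m, hb_d, gt, kr, kni) on
               each gene; dimensionless.
    M          (4, 4) weights of maternal inputs (bcd, cad, tll, hkb);
               the bcd column is the set of Bcd interaction parameters
               zeroed during illumination.
    h          (4,) basal offsets.
    R          (4,) maximal production rates, conc/min.
    lam        (4,) linear decay rates, 1/min.
    D          (4,) diffusion coefficients, %EL^2/min.
    K_hb       Hb dimer dissociation constant, conc.
    """

    T: np.ndarray
    M: np.ndarray
    h: np.ndarray
    R: np.ndarray
    lam: np.ndarray
    D: np.ndarray
    K_hb: float
    genes: tuple = GENES
    params_id: str = "unnamed"

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.genes)
        if self.T.shape != (n, len(REGULATORS)):
            raise InvalidInputError(f"T must have shape {(n, len(REGULATORS))}")
        if self.M.shape != (n, len(MATERNAL_INPUTS)):
            raise InvalidInputError(f"M must have shape {(n, len(MATERNAL_INPUTS))}")
        for name in ("h", "R", "lam", "D"):
            if getattr(self, name).shape != (n,):
                raise InvalidInputError(f"{name} must have shape ({n},)")
        arrays = [self.T, self.M, self.h, self.R, self.lam, self.D]
        if not all(np.isfinite(a).all() for a in arrays) or not np.isfinite(self.K_hb):
            raise InvalidInputError("all parameters must be finite")
        if np.any(self.lam <= 0):
            raise InvalidInputError("decay rates lam must be positive")
        if np.any(self.R < 0) or np.any(self.D < 0):
            raise InvalidInputError("R and D must be non-negative")
        if self.K_hb <= 0:
            raise InvalidInputError("K_hb must be positive")

    # -- flattening for ensemble statistics ---------------------------------

    def flatten(self) -> tuple[list[str], np.ndarray]:
        """Return (names, values) of every scalar parameter.

        The ordering is stable across calls and across parameter sets, which
        is what per-parameter ensemble z-scores rely on.
        """
        names: list[str] = []
        values: list[float] = []
        for i, g in enumerate(self.genes):
            for j, r in enumerate(REGULATORS):
                names.append(f"T[{r}->{g}]")
                values.append(self.T[i, j])
        for i, g in enumerate(self.genes):
            for j, m in enumerate(MATERNAL_INPUTS):
                names.append(f"M[{m}->{g}]")
                values.append(self.M[i, j])
        for vec, label in ((self.h, "h"), (self.R, "R"), (self.lam, "lam"), (self.D, "D")):
            for i, g in enumerate(self.genes):
                names.append(f"{label}[{g}]")
                values.append(vec[i])
        names.append("K_hb")
        values.append(self.K_hb)
        return names, np.array(values)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "regulators": list(REGULATORS),
            "maternal_inputs": list(MATERNAL_INPUTS),
            "T": self.T.tolist(),
            "M": self.M.tolist(),
            "h": self.h.tolist(),
            "R": self.R.tolist(),
            "lam": self.lam.tolist(),
            "D": self.D.tolist(),
            "K_hb": self.K_hb,
            "params_id": self.params_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        return cls(
            T=np.array(d["T"]), M=np.array(d["M"]), h=np.array(d["h"]),
            R=np.array(d["R"]), lam=np.array(d["lam"]), D=np.array(d["D"]),
            K_hb=float(d["K_hb"]), genes=tuple(d.get("genes", GENES)),
            params_id=d.get("params_id", "unnamed"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class MaternalField:
    """Static maternal-input profiles over an :class:`AxisGrid`."""

    grid: AxisGrid
    profiles: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in MATERNAL_INPUTS:
            if name not in self.profiles:
                raise InvalidInputError(f"missing maternal profile '{name}'")
            arr = np.asarray(self.profiles[name], dtype=float)
            if arr.shape != (self.grid.n_bins,):
                raise InvalidInputError(
                    f"profile '{name}' length {arr.shape} does not match grid"
                )
            if np.any(arr < 0):
                raise InvalidInputError(f"profile '{name}' has negative values")
            self.profiles[name] = arr

    def as_matrix(self) -> np.ndarray:
        """(n_inputs, n_bins) matrix in canonical input order."""
        return np.stack([self.profiles[name] for name in MATERNAL_INPUTS])


@dataclass
class Trajectory:
    """Stored states of a simulation on the gastrulation-anchored clock."""

    times: np.ndarray          # (n_times,) minutes, strictly increasing, <= 0
    states: np.ndarray         # (n_times, n_genes, n_bins)
    grid: AxisGrid
    params_id: str = "unnamed"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.times[-1] > 0:
            raise InvalidInputError("final time must be <= 0 (gastrulation)")
        if np.any(self.states < -1e-9):
            raise InvalidInputError("concentrations below numerical tolerance")

    def state_at(self, t: float) -> np.ndarray:
        """State at the stored time nearest to ``t``."""
        return self.states[int(np.argmin(np.abs(self.times - t)))]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Long-format table: time, gene, bin, %EL, value."""
        import pandas as pd

        n_t, n_g, n_b = self.states.shape
        pos = self.grid.positions
        return pd.DataFrame({
            "time_min": np.repeat(self.times, n_g * n_b),
            "gene": np.tile(np.repeat(list(GENES), n_b), n_t),
            "bin": np.tile(np.arange(n_b), n_t * n_g),
            "percent_el": np.tile(pos, n_t * n_g),
            "value": self.states.ravel(),
        })


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sigmoid(u):
    """Gene-circuit activation function Phi(u) = (u / sqrt(u^2 + 1) + 1) / 2.

    Strictly within (0, 1), monotone increasing, with the antisymmetry
    Phi(-u) = 1 - Phi(u) and Phi(0) = 1/2.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise InvalidInputError("sigmoid input must be finite")
    out = 0.5 * (u / np.sqrt(u * u + 1.0) + 1.0)
    return float(out) if out.ndim == 0 else out


def hb_partition(v_total, K_hb: float):
    """Split total Hb into monomer and dimer at mass-action equilibrium.

    Solves monomer^2 / dimer = K_hb with monomer + 2 * dimer = v_total,
    whose physical root is monomer = (-K + sqrt(K^2 + 8 K v)) / 4.
    """
    v = np.asarray(v_total, dtype=float)
    if K_hb <= 0:
        raise InvalidInputError("K_hb must be positive")
    if np.any(v < 0):
        raise InvalidInputError("total Hb concentration must be non-negative")
    monomer = 0.25 * (-K_hb + np.sqrt(K_hb * K_hb + 8.0 * K_hb * v))
    dimer = 0.5 * (v - monomer)
    dimer = np.maximum(dimer, 0.0)  # guard round-off at v ~ 0
    if v.ndim == 0:
        return float(monomer), float(dimer)
    return monomer, dimer


def regulatory_input(state: np.ndarray, maternal: MaternalField,
                     params: CircuitParams, bcd_active: bool = True) -> np.ndarray:
    """Total regulatory input u_a(x) for every gene and bin.

    u = T @ [hb_m, hb_d, gt, kr, kni] + M @ [bcd, cad, tll, hkb] + h,
    with the Bcd column of M contributing exactly zero when ``bcd_active``
    is false (instantaneous optogenetic shutdown semantics).
    """
    state = np.asarray(state, dtype=float)
    n = len(params.genes)
    if state.shape != (n, maternal.grid.n_bins):
        raise InvalidInputError(
            f"state shape {state.shape} does not match "
            f"({n}, {maternal.grid.n_bins})"
        )
    hb_m, hb_d = hb_partition(state[0], params.K_hb)
    regulators = np.stack([hb_m, hb_d, state[1], state[2], state[3]])
    g = maternal.as_matrix()
    M_eff = params.M if bcd_active else _bcd_silenced(params.M)
    return params.T @ regulators + M_eff @ g + params.h[:, None]


def _bcd_silenced(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    out[:, BCD_INDEX] = 0.0
    return out


def simulate(params: CircuitParams, maternal: MaternalField,
             scenario: IlluminationScenario | None = None,
             grid: AxisGrid | None = None,
             t_start: float = -90.0, t_end: float = 0.0, dt: float = 0.01,
             v0: np.ndarray | None = None,
             save_every: float = 1.0) -> Trajectory:
    """Integrate the circuit over [t_start, t_end].

    The production/decay part uses an exponential-Euler update — exact
    for the linear decay, so pure-decay solutions and frozen-input fixed
    points are reproduced to round-off rather than O(dt):

        v <- v e^(-lam dt) + R Phi(u) (1 - e^(-lam dt)) / lam + dt D lap(v)

    Diffusion uses central differences with no-flux (reflecting)
    boundaries and remains subject to the explicit stability bound.
    ``scenario`` gives the illumination windows during which all Bcd
    interactions are silenced; ``None`` or an empty scenario is the dark
    control.  States are stored every ``save_every`` minutes (plus the
    endpoint).

    Raises
    ------
    ConfigurationError
        If dt violates the diffusion stability bound dt < w^2 / (2 max D).
    NumericalFailureError
        If a non-finite state is encountered; the exception names the time.
    """
    grid = grid or maternal.grid
    if grid.n_bins != maternal.grid.n_bins:
        raise InvalidInputError("grid does not match maternal field grid")
    if not (t_start < t_end <= 0):
        raise InvalidInputError("require t_start < t_end <= 0")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    w = grid.bin_width
    Dmax = float(params.D.max())
    if Dmax > 0 and dt >= w * w / (2.0 * Dmax):
        raise ConfigurationError(
            f"dt={dt} violates diffusion stability bound "
            f"{w * w / (2.0 * Dmax):.4g} min"
        )
    n_genes = len(params.genes)
    if v0 is None:
        v = np.zeros((n_genes, grid.n_bins))
    else:
        v = np.array(v0, dtype=float)
        if v.shape != (n_genes, grid.n_bins):
            raise InvalidInputError("v0 shape does not match (genes, bins)")
        if np.any(v < 0):
            raise InvalidInputError("v0 must be non-negative")

    n_steps = int(round((t_end - t_start) / dt))
    save_stride = max(1, int(round(save_every / dt)))
    windows = scenario.windows if scenario is not None else []

    g = maternal.as_matrix()
    M_dark = params.M
    M_lit = _bcd_silenced(params.M)
    R = params.R[:, None]
    Dcoef = params.D[:, None] / (w * w)
    h = params.h[:, None]
    decay = np.exp(-params.lam * dt)[:, None]
    gain = ((1.0 - np.exp(-params.lam * dt)) / params.lam)[:, None]

    times = [t_start]
    states = [v.copy()]
    for step in range(n_steps):
        t = t_start + step * dt
        illuminated = any(s <= t < e for s, e in windows)
        M_eff = M_lit if illuminated else M_dark
        hb_m, hb_d = hb_partition(v[0], params.K_hb)
        regulators = np.stack([hb_m, hb_d, v[1], v[2], v[3]])
        with np.errstate(over="ignore", invalid="ignore"):
            u = params.T @ regulators + M_eff @ g + h
        try:
            production = R * sigmoid(u)
        except InvalidInputError:
            raise NumericalFailureError(
                f"non-finite regulatory input at t = {t:.3f} min", time=t
            ) from None
        vp = np.pad(v, ((0, 0), (1, 1)), mode="edge")
        lap = vp[:, :-2] - 2.0 * v + vp[:, 2:]
        v = v * decay + production * gain + dt * Dcoef * lap
        if (step + 1) % save_stride == 0 or step == n_steps - 1:
            t_next = t_start + (step + 1) * dt
            if not np.all(np.isfinite(v)):
                raise NumericalFailureError(
                    f"non-finite state at t = {t_next:.3f} min", time=t_next
                )
            if times[-1] < t_next - 1e-12:
                times.append(t_next)
                states.append(v.copy())
    return Trajectory(times=np.array(times), states=np.array(states),
                      grid=grid, params_id=params.params_id)


def steady_state_closed_form(params: CircuitParams, u_const: float,
                             gene: int) -> float:
    """Fixed point R * Phi(u) / lam of the well-mixed rate equation."""
    lam = params.lam[gene]
    if lam <= 0:
        raise InvalidInputError("decay rate must be positive")
    return params.R[gene] * sigmoid(u_const) / lam
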