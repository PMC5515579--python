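"""Scenario batteries, perturbation scoring, and parameter-ensemble statistics.

Runs the gap-gene circuit under a battery of illumination scenarios,
compares end-of-simulation (gastrulation) expression profiles against the
dark control, scores five qualitative criteria describing how Bcd
shutdown reshapes the gap-gene pattern, and summarises how a selected
subset of a parameter ensemble differs from the full ensemble through
per-parameter z-scores.

The five criteria (evaluated perturbed-vs-dark):

  i    anterior shift of the Kr anterior boundary
  ii   anterior shift of the anterior boundary of the Kni posterior domain
  iii  reduction of Kni anterior (cap) expression
  iv   reduction of Gt anterior expression
  v    anterior shift of the posterior boundary of the anterior Hb domain
       AND reduction of anterior Hb expression (conjunctive)

Boundary shifts are signed in %EL with anterior = positive (position
values increase toward the anterior pole); level changes are fractions of
the control anterior-domain peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import GENES, CircuitParams, MaternalField, Trajectory, simulate
from .errors import DomainNotFoundError, InvalidInputError
from .profiles import DEFAULT_DOMAINS, ExpressionProfile, boundary_position
from .timeline import IlluminationScenario


@dataclass(frozen=True)
class CriterionThresholds:
    """Decision thresholds for the five perturbation criteria.

    A boundary shift counts when it moves anteriorly by at least
    ``shift_el`` %EL; a level change counts when the anterior-domain peak
    drops by at least ``level_reduction_frac`` of its control value.
    Phenotypes of this kind are traditionally scored by eye; these
    numeric defaults are this package's codification and are reported
    alongside results.
    """

    shift_el: float = 1.0
    level_reduction_frac: float = 0.10
    domains: dict = field(default_factory=lambda: dict(DEFAULT_DOMAINS))


@dataclass
class CriterionReport:
    """Measured shift/level quantities and the five criterion booleans."""

    scenario_id: str
    criteria: dict               # {"i": bool, ..., "v": bool}
    measured: dict               # named signed shifts (%EL) / level changes
    thresholds: CriterionThresholds

    @property
    def n_met(self) -> int:
        return sum(bool(v) for v in self.criteria.values())


@dataclass
class EnsembleScore:
    parameter_set_id: str
    n_criteria_met: int
    member_of_subset: bool = False


@dataclass
class ZScoreResult:
    """Per-parameter z-scores of a subset against the full ensemble.

    z_i = (<p_i over all> - <p_i over subset>) / (sigma_i_all / sqrt(n)),
    with n the full-ensemble size and sigma the sample standard deviation.
    Positive z means the subset mean lies below the ensemble mean.
    Parameters constant across the ensemble (sigma = 0) get z = 0 and are
    flagged degenerate.
    """

    names: list
    z: np.ndarray
    degenerate: np.ndarray       # boolean mask, sigma == 0

    def as_series(self):
        import pandas as pd

        return pd.Series(self.z, index=self.names, name="z")


# ---------------------------------------------------------------------------
# scenario batteries
# ---------------------------------------------------------------------------


def run_scenarios(params: CircuitParams, maternal: MaternalField,
                  scenarios: list, **simulate_kwargs) -> dict:
    """Simulate every scenario; dark control first in the returned mapping.

    Requires the battery to include a dark control (a scenario with no
    illumination windows).  Simulation failures are re-raised with the
    offending scenario id attached.
    """
    if not scenarios:
        raise InvalidInputError("scenario battery is empty")
    dark = [s for s in scenarios if not s.windows]
    if not dark:
        raise InvalidInputError("battery must include the dark control")
    ordered = dark + [s for s in scenarios if s.windows]
    out: dict = {}
    for scen in ordered:
        try:
            out[scen.id] = simulate(params, maternal, scenario=scen,
                                    **simulate_kwargs)
        except Exception as exc:
            raise type(exc)(f"scenario {scen.id}: {exc}") from exc
    return out


def trajectory_profiles(traj: Trajectory) -> dict:
    """End-state (t = 0) expression profile of each gene."""
    final = traj.final_state
    pos = traj.grid.positions
    return {g: ExpressionProfile(positions=pos, values=final[i])
            for i, g in enumerate(GENES)}


# ---------------------------------------------------------------------------
# criterion scoring
# ---------------------------------------------------------------------------


def _anterior_level(profile: ExpressionProfile, window) -> float:
    sel = (profile.positions >= window[0]) & (profile.positions <= window[1])
    if not sel.any():
        raise InvalidInputError("anterior window contains no bins")
    return float(np.nanmax(profile.values[sel]))


def _shift(control: ExpressionProfile, perturbed: ExpressionProfile,
           side: str, domain) -> float:
    """Signed boundary shift, %EL; NaN if the perturbed domain vanished."""
    b0 = boundary_position(control, side, domain)
    try:
        b1 = boundary_position(perturbed, side, domain)
    except DomainNotFoundError:
        return float("nan")
    return b1 - b0


def score_criteria(control: dict, perturbed: dict,
                   thresholds: CriterionThresholds | None = None,
                   scenario_id: str = "?") -> CriterionReport:
    """Score the five qualitative perturbation criteria.

    ``control`` and ``perturbed`` map gene name -> end-state
    :class:`ExpressionProfile` on a shared grid.  Domains missing from
    the *control* raise :class:`DomainNotFoundError`; a domain that
    vanishes only in the perturbed profiles yields a NaN shift and a
    False shift-criterion.
    """
    th = thresholds or CriterionThresholds()
    dom = th.domains

    kr_ant = _shift(control["kr"], perturbed["kr"], "anterior", dom["kr"])
    kr_post = _shift(control["kr"], perturbed["kr"], "posterior", dom["kr"])
    kni_ant = _shift(control["kni"], perturbed["kni"], "anterior",
                     dom["kni_posterior"])
    kni_post = _shift(control["kni"], perturbed["kni"], "posterior",
                      dom["kni_posterior"])
    hb_post = _shift(control["hb"], perturbed["hb"], "posterior",
                     dom["hb_anterior"])

    def level_change(gene: str, window) -> float:
        ref = _anterior_level(control[gene], window)
        if ref <= 0:
            raise DomainNotFoundError(f"no {gene} anterior expression in control")
        return (_anterior_level(perturbed[gene], window) - ref) / ref

    kni_level = level_change("kni", dom["kni_anterior"])
    gt_level = level_change("gt", dom["gt_anterior"])
    hb_level = level_change("hb", dom["hb_anterior"])

    def shifted(delta: float) -> bool:
        return bool(np.isfinite(delta) and delta >= th.shift_el)

    def reduced(change: float) -> bool:
        return bool(change <= -th.level_reduction_frac)

    criteria = {
        "i": shifted(kr_ant),
        "ii": shifted(kni_ant),
        "iii": reduced(kni_level),
        "iv": reduced(gt_level),
        "v": shifted(hb_post) and reduced(hb_level),
    }
    measured = {
        "kr_anterior_shift_el": kr_ant,
        "kr_posterior_shift_el": kr_post,
        "kni_anterior_shift_el": kni_ant,
        "kni_posterior_shift_el": kni_post,
        "hb_posterior_shift_el": hb_post,
        "kni_anterior_level_change": kni_level,
        "gt_anterior_level_change": gt_level,
        "hb_anterior_level_change": hb_level,
    }
    return CriterionReport(scenario_id=scenario_id, criteria=criteria,
                           measured=measured, thresholds=th)


def select_subset(scores: list, min_criteria: int = 3) -> list:
    """Ids of parameter sets meeting at least ``min_criteria`` criteria.

    Preserves input order and marks ``member_of_subset`` on the scores.
    """
    if not scores:
        raise InvalidInputError("scores must be non-empty")
    subset = []
    for s in scores:
        s.member_of_subset = s.n_criteria_met >= min_criteria
        if s.member_of_subset:
            subset.append(s.parameter_set_id)
    return subset


# ---------------------------------------------------------------------------
# ensemble z-scores
# ---------------------------------------------------------------------------


def param_zscore(all_params: list, subset_ids: list,
                 denominator: str = "sqrt_n") -> ZScoreResult:
    """Per-parameter z-score of a subset against the full ensemble.

    ``denominator`` selects sigma/sqrt(n) (default) or sigma/n, n being
    the full-ensemble size.  The sign convention is <all> - <subset>:
    positive when the subset mean lies below the ensemble mean.
    """
    if not subset_ids:
        raise InvalidInputError("subset must be non-empty")
    ids = [p.params_id for p in all_params]
    missing = [s for s in subset_ids if s not in ids]
    if missing:
        raise InvalidInputError(f"subset ids not in ensemble: {missing}")
    names, _ = all_params[0].flatten()
    values = np.stack([p.flatten()[1] for p in all_params])
    subset_mask = np.array([i in set(subset_ids) for i in ids])
    n = len(all_params)
    mean_all = values.mean(axis=0)
    mean_subset = values[subset_mask].mean(axis=0)
    sigma = values.std(axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    if denominator == "sqrt_n":
        denom = sigma / np.sqrt(n)
    elif denominator == "n":
        denom = sigma / n
    else:
        raise InvalidInputError("denominator must be 'sqrt_n' or 'n'")
    degenerate = sigma == 0
    z = np.zeros_like(mean_all)
    ok = ~degenerate
    z[ok] = (mean_all[ok] - mean_subset[ok]) / denom[ok]
    return ZScoreResult(names=names, z=z, degenerate=degenerate)


def zscore_matrix(result: ZScoreResult):
    """Interaction z-scores as a regulator-by-target-gene table.

    Rows are interacting elements (gap-gene forms and maternal inputs),
    columns the four target genes; entries are the z-scores of the T and
    M weights, mirroring the heat-map layout used for ensemble refinement.
    """
    import pandas as pd

    table: dict = {}
    for name, z in zip(result.names, result.z):
        if name.startswith(("T[", "M[")):
            inner = name[2:-1]
            reg, gene = inner.split("->")
            table.setdefault(reg, {})[gene] = z
    return pd.DataFrame(table).T.reindex(columns=list(GENES))
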