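"""Input-variability scenario analysis: the process "risk fingerprint".

Four scenario sets probe how the maximum LOD of a calibrated process
responds to coordinated setpoint deviations of the three deviatable
process parameters (inlet air temperature, inlet air flow, spray rate),
each run at three inlet-humidity levels and in both the "wet" direction
(all offsets raising the maximum LOD) and the "dry" direction:

=====  ==================================================================
I      every nonempty parameter subset x every nonempty spray-subphase
       subset at a fixed 2 sigma magnitude — minor-malfunction survey
II     one parameter in one subphase, magnitude searched over 1..30
       sigma — time sensitivity of the maximum LOD
III    six 5-minute pulses across the spray phase, 1-3 parameters,
       magnitude searched over 1..20 sigma — controller glitches
IV     one parameter offset for the whole spray phase, searched over
       1..20 sigma — sensor calibration offset
=====  ==================================================================

Set I is summarized as the fraction of runs leaving the maximum-LOD
design space per deviation score (#parameters x #subphases affected);
sets II-IV as the maximum tolerable deviation sigma* per scenario.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .recipe_model import (
    DesignSpace,
    ParameterStdDevs,
    PARAM_NAMES,
    Recipe,
    RecipeValidationError,
    apply_disturbance,
    deviation_direction_signs,
    make_profile,
    select_recipe_by_humidity,
    total_binder_solution,
)
from .simulator import ModelParameters, simulate
from .thermo import EquipmentProperties, MaterialProperties

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "MaxTolerableResult",
    "RiskFingerprint",
    "deviation_direction_signs",
    "deviation_score",
    "build_scenarios",
    "scenario_recipe",
    "run_scenario",
    "fraction_out_by_score",
    "max_tolerable_deviation",
    "risk_fingerprint",
    "center_recipe",
    "SEARCH_RANGES",
    "PULSE_DURATION",
    "N_PULSES",
]

#: Integer sigma search grids per scenario set.
SEARCH_RANGES: Mapping[str, tuple[int, ...]] = {
    "II": tuple(range(1, 31)),
    "III": tuple(range(1, 21)),
    "IV": tuple(range(1, 21)),
}

PULSE_DURATION = 300.0  # 5-minute pulses in set III
N_PULSES = 6            # totalling 30 min of disturbance

DEFAULT_HUMIDITY_LEVELS = (1.0, 5.0, 10.0)  # g/kg


@dataclass(frozen=True)
class ScenarioSpec:
    """One disturbance scenario: what deviates, where, how much.

    ``magnitude`` is the fixed deviation in sigma units, or ``None`` when
    the scenario searches for the maximum tolerable magnitude over
    ``search_range``.  ``subphases`` are 0-based spray-subphase indices;
    ``pulses`` are (start, duration) windows [s] relative to spray start.
    """

    set_id: str
    direction: str
    humidity_gkg: float
    params: tuple[str, ...]
    magnitude: float | None = None
    subphases: tuple[int, ...] | None = None
    pulses: tuple[tuple[float, float], ...] | None = None
    search_range: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(self.params))
        if self.subphases is not None:
            object.__setattr__(self, "subphases", tuple(self.subphases))
        if self.pulses is not None:
            object.__setattr__(self, "pulses",
                               tuple((float(a), float(b)) for a, b in self.pulses))
        if self.set_id == "I" and self.params and self.magnitude != 2.0:
            raise ValueError("set I uses the fixed 2 sigma magnitude")


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    lod_max: float
    in_design_space: bool
    score: int


@dataclass(frozen=True)
class MaxTolerableResult:
    """Outcome of a sigma* search for one sets-II-IV scenario.

    ``sigma_star`` is the largest grid magnitude keeping the maximum LOD
    inside the design space (``None`` when the undisturbed run is already
    outside); ``capped`` marks searches that never left the space within
    the grid.
    """

    spec: ScenarioSpec
    sigma_star: int | None
    capped: bool
    nominal_in_range: bool
    lod_max_nominal: float


def deviation_score(spec: ScenarioSpec) -> int:
    """(#parameters varied) x (#spray subphases affected).

    Pulse scenarios count one affected window pattern, so their score is
    the number of deviated parameters; a zero-magnitude or parameter-free
    scenario scores 0.
    """
    if not spec.params or spec.magnitude == 0.0:
        return 0
    n_phases = len(spec.subphases) if spec.subphases is not None else 1
    return len(spec.params) * n_phases


def _pulse_windows(recipe: Recipe) -> tuple[tuple[float, float], ...]:
    """Six 5-min pulses uniformly distributed over the spray stage."""
    s0, s1 = recipe.spray_window()
    span = s1 - s0
    slot = span / N_PULSES
    dur = min(PULSE_DURATION, slot)
    return tuple((i * slot + (slot - dur) / 2.0, dur) for i in range(N_PULSES))


def build_scenarios(
    set_id: str,
    recipe: Recipe,
    humidity_levels: Sequence[float] = DEFAULT_HUMIDITY_LEVELS,
    directions: Sequence[str] = ("wet", "dry"),
) -> list[ScenarioSpec]:
    """Enumerate one scenario set for a recipe.

    Set I yields every (nonempty parameter subset) x (nonempty subphase
    subset) combination at 2 sigma — 217 specs per direction per humidity
    for 3 parameters and 5 subphases; sets II-IV yield search templates
    with ``magnitude=None``.
    """
    n_sub = recipe.n_spray_subphases
    if n_sub == 0:
        raise RecipeValidationError("recipe has no spray subphases to disturb")
    out: list[ScenarioSpec] = []
    for hum in humidity_levels:
        for direction in directions:
            if set_id == "I":
                for k in range(1, len(PARAM_NAMES) + 1):
                    for params in itertools.combinations(PARAM_NAMES, k):
                        for f in range(1, n_sub + 1):
                            for sub in itertools.combinations(range(n_sub), f):
                                out.append(ScenarioSpec(
                                    "I", direction, hum, params,
                                    magnitude=2.0, subphases=sub,
                                ))
            elif set_id == "II":
                for param in PARAM_NAMES:
                    for i in range(n_sub):
                        out.append(ScenarioSpec(
                            "II", direction, hum, (param,), subphases=(i,),
                            search_range=SEARCH_RANGES["II"],
                        ))
            elif set_id == "III":
                pulses = _pulse_windows(recipe)
                for k in range(1, len(PARAM_NAMES) + 1):
                    for params in itertools.combinations(PARAM_NAMES, k):
                        out.append(ScenarioSpec(
                            "III", direction, hum, params, pulses=pulses,
                            search_range=SEARCH_RANGES["III"],
                        ))
            elif set_id == "IV":
                for param in PARAM_NAMES:
                    out.append(ScenarioSpec(
                        "IV", direction, hum, (param,),
                        subphases=tuple(range(n_sub)),
                        search_range=SEARCH_RANGES["IV"],
                    ))
            else:
                raise ValueError(f"unknown scenario set {set_id!r}")
    return out


def scenario_recipe(
    recipe: Recipe,
    spec: ScenarioSpec,
    sigmas: ParameterStdDevs,
    magnitude: float | None = None,
) -> Recipe:
    """Recipe with the scenario's humidity and disturbance applied."""
    mag = spec.magnitude if magnitude is None else magnitude
    base = recipe.with_humidity(spec.humidity_gkg / 1000.0)
    if not spec.params or mag in (None, 0.0):
        return base
    profile = make_profile(
        spec.direction, mag, spec.params,
        subphases=spec.subphases,
        n_subphases=recipe.n_spray_subphases,
        pulses=spec.pulses,
    )
    return apply_disturbance(base, profile, sigmas)


def run_scenario(
    recipe: Recipe,
    params: ModelParameters,
    spec: ScenarioSpec,
    sigmas: ParameterStdDevs,
    design_space: DesignSpace,
    props: MaterialProperties | None = None,
    equip: EquipmentProperties | None = None,
) -> ScenarioResult:
    """Simulate one fixed-magnitude scenario and score it."""
    disturbed = scenario_recipe(recipe, spec, sigmas)
    try:
        traj = simulate(disturbed, params, props, equip)
    except Exception as exc:
        raise RuntimeError(f"simulation failed for scenario {spec}") from exc
    lod_max = traj.lod_max
    return ScenarioResult(
        spec=spec, lod_max=lod_max,
        in_design_space=design_space.contains(lod_max),
        score=deviation_score(spec),
    )


def fraction_out_by_score(results: Iterable[ScenarioResult]) -> dict[int, float]:
    """Per deviation score, the fraction of runs outside the design space.

    Non-monotone behavior across scores is a genuine signal for sensitive
    products and is reported as-is.
    """
    totals: dict[int, int] = {}
    outs: dict[int, int] = {}
    for r in results:
        totals[r.score] = totals.get(r.score, 0) + 1
        outs[r.score] = outs.get(r.score, 0) + (0 if r.in_design_space else 1)
    return {s: outs[s] / totals[s] for s in sorted(totals)}


def max_tolerable_deviation(
    recipe: Recipe,
    params: ModelParameters,
    spec_template: ScenarioSpec,
    sigmas: ParameterStdDevs,
    design_space: DesignSpace,
    search_range: Sequence[int] | None = None,
    props: MaterialProperties | None = None,
    equip: EquipmentProperties | None = None,
) -> MaxTolerableResult:
    """Search the ascending integer sigma grid for the largest tolerable magnitude.

    Returns the magnitude preceding the first out-of-range grid point
    (0 if the very first fails, the grid top — flagged ``capped`` — if
    none fail).  An undisturbed run already outside the design space is
    returned flagged rather than raised: this legitimately happens for
    sensitive products at extreme humidity.
    """
    grid = tuple(search_range or spec_template.search_range or SEARCH_RANGES["IV"])
    if list(grid) != sorted(grid) or len(set(grid)) != len(grid):
        raise ValueError("search range must be strictly ascending")
    nominal = simulate(
        recipe.with_humidity(spec_template.humidity_gkg / 1000.0),
        params, props, equip,
    ).lod_max
    if not design_space.contains(nominal):
        return MaxTolerableResult(spec_template, None, False, False, nominal)
    sigma_star = 0
    capped = True
    for mag in grid:
        disturbed = scenario_recipe(recipe, spec_template, sigmas, magnitude=float(mag))
        lod_max = simulate(disturbed, params, props, equip).lod_max
        if not design_space.contains(lod_max):
            capped = False
            break
        sigma_star = mag
    return MaxTolerableResult(spec_template, sigma_star, capped, True, nominal)


@dataclass
class RiskFingerprint:
    """Aggregated robustness metrics across scenario sets and humidities.

    ``set_i_fraction_out``: (humidity, direction) -> {score: fraction out};
    ``set_ii`` .. ``set_iv``: per-scenario sigma* results; ``set_iii_summary``
    groups set III by deviation score with mean/sd of sigma*.
    """

    design_space: DesignSpace
    humidity_levels: tuple[float, ...]
    set_i_fraction_out: dict[tuple[float, str], dict[int, float]] = field(default_factory=dict)
    set_i_results: list[ScenarioResult] = field(default_factory=list)
    set_ii: list[MaxTolerableResult] = field(default_factory=list)
    set_iii: list[MaxTolerableResult] = field(default_factory=list)
    set_iv: list[MaxTolerableResult] = field(default_factory=list)

    def set_iii_summary(self) -> dict[tuple[float, str, int], tuple[float, float]]:
        """Per (humidity, direction, score): mean and sd of sigma*."""
        groups: dict[tuple[float, str, int], list[float]] = {}
        for r in self.set_iii:
            if r.sigma_star is None:
                continue
            key = (r.spec.humidity_gkg, r.spec.direction, len(r.spec.params))
            groups.setdefault(key, []).append(float(r.sigma_star))
        return {
            k: (float(np.mean(v)), float(np.std(v))) for k, v in sorted(groups.items())
        }


def risk_fingerprint(
    recipe: Recipe | Mapping[tuple[float, float], Recipe],
    params: ModelParameters,
    sigmas: ParameterStdDevs,
    design_space: DesignSpace,
    humidity_levels: Sequence[float] = DEFAULT_HUMIDITY_LEVELS,
    sets: Sequence[str] = ("I", "II", "III", "IV"),
    directions: Sequence[str] = ("wet", "dry"),
    props: MaterialProperties | None = None,
    equip: EquipmentProperties | None = None,
) -> RiskFingerprint:
    """Run the selected scenario sets at every humidity level and direction.

    ``recipe`` may be a single recipe or a mapping from humidity groups
    (g/kg intervals) to humidity-dependent recipes, in which case each
    level is simulated with its group's recipe.  Set I additionally runs
    the undisturbed score-0 baseline per humidity and direction.
    Fully deterministic.
    """
    def recipe_for(hum: float) -> Recipe:
        if isinstance(recipe, Recipe):
            return recipe
        return select_recipe_by_humidity(recipe, hum)

    fp = RiskFingerprint(design_space=design_space,
                         humidity_levels=tuple(humidity_levels))
    if "I" in sets:
        for hum in humidity_levels:
            r = recipe_for(hum)
            for direction in directions:
                specs = [ScenarioSpec("I", direction, hum, ())]  # score-0 baseline
                specs += build_scenarios("I", r, [hum], [direction])
                results = [
                    run_scenario(r, params, s, sigmas, design_space, props, equip)
                    for s in specs
                ]
                fp.set_i_results.extend(results)
                fp.set_i_fraction_out[(hum, direction)] = fraction_out_by_score(results)
    for set_id, store in (("II", fp.set_ii), ("III", fp.set_iii), ("IV", fp.set_iv)):
        if set_id not in sets:
            continue
        for hum in humidity_levels:
            r = recipe_for(hum)
            for template in build_scenarios(set_id, r, [hum], directions):
                store.append(max_tolerable_deviation(
                    r, params, template, sigmas, design_space,
                    props=props, equip=equip,
                ))
    return fp


def center_recipe(
    recipe: Recipe,
    params: ModelParameters,
    design_space: DesignSpace,
    props: MaterialProperties | None = None,
    equip: EquipmentProperties | None = None,
    factor_bounds: tuple[float, float] = (0.5, 2.0),
    tol: float = 1e-3,
) -> Recipe:
    """Rescale the spray rate to center the maximum LOD in the design space.

    Spray-subphase rates are multiplied by a factor f and their durations
    by 1/f, conserving the total binder solution sprayed; f is solved so
    the simulated maximum LOD hits the design-space center.  The maximum
    LOD increases monotonically with f (faster spraying outruns drying).
    """
    def scaled(f: float) -> Recipe:
        phases = tuple(
            replace(p, F_spray_set=p.F_spray_set * f, duration=p.duration / f)
            if p.kind == "spray" else p
            for p in recipe.phases
        )
        return replace(recipe, phases=phases)

    def gap(f: float) -> float:
        return simulate(scaled(f), params, props, equip).lod_max - design_space.center

    lo, hi = factor_bounds
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"cannot center: lod_max stays on one side of {design_space.center:.2f} "
            f"for spray factors in {factor_bounds}"
        )
    f_star = brentq(gap, lo, hi, xtol=tol)
    out = scaled(f_star)
    assert abs(total_binder_solution(out) - total_binder_solution(recipe)) < 1e-9
    return out
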