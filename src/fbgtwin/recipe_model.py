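"""Recipes, batch records, design spaces and input-disturbance profiles.

A granulation recipe is an ordered list of phases (premix, spray, dry; the
spray and dry stages may be split into subphases with distinct setpoints)
plus the initial charge, initial moisture and binder-solution composition.
Disturbance profiles express setpoint offsets in units of each process
parameter's typical standard deviation, either per spray subphase or as
pulse windows inside the spray stage.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "Recipe",
    "LODSample",
    "BatchRecord",
    "DesignSpace",
    "DisturbanceProfile",
    "ParameterStdDevs",
    "RecipeValidationError",
    "PARAM_NAMES",
    "read_recipe",
    "write_recipe",
    "read_batch_samples",
    "write_batch_samples",
    "apply_disturbance",
    "make_profile",
    "select_recipe_by_humidity",
    "total_binder_solution",
]

#: Deviatable process parameters (inlet air temperature, inlet air flow,
#: spray rate) in canonical order.
PARAM_NAMES = ("T_in", "F_air", "F_spray")

PHASE_KINDS = ("premix", "spray", "dry")


class RecipeValidationError(ValueError):
    """A recipe, phase or profile violates a structural invariant."""


@dataclass(frozen=True)
class Phase:
    """One constant-setpoint segment of a granulation recipe.

    ``duration`` [s]; ``T_in_set`` inlet air temperature [degC];
    ``F_air_set`` dry-air mass flow [kg/s]; ``F_spray_set`` binder-solution
    mass flow [kg/s] (zero except in spray phases); ``x_in`` inlet air
    mixing ratio [kg water / kg dry air].
    """

    name: str
    kind: str
    duration: float
    T_in_set: float
    F_air_set: float
    F_spray_set: float = 0.0
    x_in: float = 0.005

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise RecipeValidationError(f"phase {self.name!r}: unknown kind {self.kind!r}")
        if not self.duration > 0:
            raise RecipeValidationError(f"phase {self.name!r}: duration must be > 0")
        for f in ("F_air_set", "F_spray_set", "x_in"):
            if getattr(self, f) < 0:
                raise RecipeValidationError(f"phase {self.name!r}: {f} must be >= 0")
        if self.kind != "spray" and self.F_spray_set != 0.0:
            raise RecipeValidationError(
                f"phase {self.name!r}: F_spray_set must be 0 in a {self.kind} phase"
            )


@dataclass(frozen=True)
class Recipe:
    """A full granulation recipe: phases plus charge and initial state.

    ``m_solids_0`` initial dry solids charge [kg]; ``lod_0`` initial
    loss-on-drying [%]; ``w_s`` binder solids weight fraction;
    ``T_spray`` spray liquid temperature [degC]; ``T_*_0`` initial
    bed/air/wall temperatures [degC].
    """

    phases: tuple[Phase, ...]
    m_solids_0: float
    lod_0: float = 2.0
    w_s: float = 0.08
    T_spray: float = 25.0
    T_bed_0: float = 22.0
    T_air_0: float = 22.0
    T_wall_0: float = 22.0
    name: str = "recipe"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise RecipeValidationError("recipe must contain at least one phase")
        if not self.m_solids_0 > 0:
            raise RecipeValidationError("m_solids_0 must be positive")
        if not 0.0 <= self.w_s < 1.0:
            raise RecipeValidationError("w_s must lie in [0, 1)")
        if not 0.0 <= self.lod_0 < 100.0:
            raise RecipeValidationError("lod_0 must lie in [0, 100)")
        spray_idx = [i for i, p in enumerate(self.phases) if p.kind == "spray"]
        if spray_idx and spray_idx != list(range(spray_idx[0], spray_idx[-1] + 1)):
            raise RecipeValidationError("spray subphases must be contiguous")

    # -- convenience views -------------------------------------------------

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def spray_indices(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.phases) if p.kind == "spray")

    @property
    def n_spray_subphases(self) -> int:
        return len(self.spray_indices)

    def phase_start_times(self) -> list[float]:
        """Absolute start time [s] of each phase."""
        out, t = [], 0.0
        for p in self.phases:
            out.append(t)
            t += p.duration
        return out

    def spray_window(self) -> tuple[float, float]:
        """Absolute (start, end) [s] of the spray stage."""
        starts = self.phase_start_times()
        idx = self.spray_indices
        if not idx:
            raise RecipeValidationError(f"recipe {self.name!r} has no spray phase")
        return starts[idx[0]], starts[idx[-1]] + self.phases[idx[-1]].duration

    def with_humidity(self, x_in: float) -> "Recipe":
        """Copy of the recipe with every phase's inlet mixing ratio set to ``x_in`` [kg/kg]."""
        return replace(self, phases=tuple(replace(p, x_in=x_in) for p in self.phases))


def total_binder_solution(recipe: Recipe) -> float:
    """Total sprayed binder-solution mass [kg] over all spray subphases."""
    return sum(p.F_spray_set * p.duration for p in recipe.phases if p.kind == "spray")


@dataclass(frozen=True)
class LODSample:
    """One timestamped loss-on-drying measurement (``t`` [s], ``lod`` [%])."""

    t: float
    lod: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise RecipeValidationError("sample time must be >= 0")
        if not 0.0 <= self.lod < 100.0:
            raise RecipeValidationError("LOD must lie in [0, 100)")


@dataclass(frozen=True)
class BatchRecord:
    """A manufactured batch: its recipe and the measured LOD samples."""

    recipe: Recipe
    samples: tuple[LODSample, ...]
    label: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        total = self.recipe.total_duration
        times = [s.t for s in self.samples]
        if any(t > total + 1e-9 for t in times):
            raise RecipeValidationError(
                f"batch {self.label!r}: sample beyond recipe duration {total} s"
            )
        if times != sorted(times):
            raise RecipeValidationError(f"batch {self.label!r}: samples must be time-ordered")

    @property
    def sample_times(self) -> list[float]:
        return [s.t for s in self.samples]

    @property
    def sample_lods(self) -> list[float]:
        return [s.lod for s in self.samples]


@dataclass(frozen=True)
class DesignSpace:
    """Acceptable interval for the maximum LOD reached during a run [%]."""

    lod_max_lo: float
    lod_max_hi: float

    def __post_init__(self) -> None:
        if not self.lod_max_lo < self.lod_max_hi:
            raise RecipeValidationError("design space must satisfy lod_max_lo < lod_max_hi")

    def contains(self, lod_max: float) -> bool:
        return self.lod_max_lo <= lod_max <= self.lod_max_hi

    @property
    def center(self) -> float:
        return 0.5 * (self.lod_max_lo + self.lod_max_hi)

    @property
    def width(self) -> float:
        return self.lod_max_hi - self.lod_max_lo


@dataclass(frozen=True)
class ParameterStdDevs:
    """Typical standard deviation of each deviatable process parameter.

    ``sigma_T_in`` [degC], ``sigma_F_air`` [kg/s], ``sigma_F_spray`` [kg/s];
    one value per parameter, shared by every phase.
    """

    sigma_T_in: float = 1.0
    sigma_F_air: float = 0.01
    sigma_F_spray: float = 4.0e-4

    def __post_init__(self) -> None:
        for f in ("sigma_T_in", "sigma_F_air", "sigma_F_spray"):
            if not getattr(self, f) > 0:
                raise RecipeValidationError(f"{f} must be positive")

    def of(self, param: str) -> float:
        return {"T_in": self.sigma_T_in, "F_air": self.sigma_F_air,
                "F_spray": self.sigma_F_spray}[param]


#: Offset signs that raise the maximum LOD ("wet" deviation): more spray,
#: colder and slower drying air.  A "dry" deviation is the exact negation.
WET_SIGNS: Mapping[str, float] = {"F_spray": +1.0, "T_in": -1.0, "F_air": -1.0}


def deviation_direction_signs(direction: str) -> dict[str, float]:
    """Per-parameter offset sign for a coordinated wet or dry deviation."""
    if direction == "wet":
        return dict(WET_SIGNS)
    if direction == "dry":
        return {k: -v for k, v in WET_SIGNS.items()}
    raise ValueError(f"unknown deviation direction {direction!r}")


@dataclass(frozen=True)
class DisturbanceProfile:
    """Signed setpoint offsets, in sigma units, applied to a recipe.

    ``offsets`` maps a parameter name to a per-spray-subphase tuple of
    offsets (sigma units, signed).  If ``pulses`` is given, each
    parameter's offset must be uniform and is applied only inside the
    pulse windows (``(start, duration)`` [s] relative to spray start).
    All nonzero offsets must share the sign pattern of ``direction``.
    """

    offsets: Mapping[str, tuple[float, ...]]
    direction: str = "wet"
    pulses: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "offsets", {k: tuple(v) for k, v in self.offsets.items()}
        )
        signs = deviation_direction_signs(self.direction)
        for param, offs in self.offsets.items():
            if param not in PARAM_NAMES:
                raise RecipeValidationError(f"unknown process parameter {param!r}")
            for o in offs:
                if o != 0.0 and math.copysign(1.0, o) != signs[param]:
                    raise RecipeValidationError(
                        f"offset {o} on {param} contradicts a {self.direction} deviation"
                    )
        if self.pulses is not None:
            object.__setattr__(self, "pulses", tuple((float(a), float(b)) for a, b in self.pulses))
            for start, dur in self.pulses:
                if start < 0 or dur <= 0:
                    raise RecipeValidationError("pulse windows need start >= 0 and duration > 0")


def make_profile(
    direction: str,
    magnitude: float,
    params: Iterable[str],
    *,
    subphases: Iterable[int] | None = None,
    n_subphases: int | None = None,
    pulses: Sequence[tuple[float, float]] | None = None,
) -> DisturbanceProfile:
    """Build a profile with ``magnitude`` sigma on ``params``.

    Either ``subphases`` (0-based indices among ``n_subphases`` spray
    subphases) or ``pulses`` must be given.  Signs follow ``direction``.
    """
    signs = deviation_direction_signs(direction)
    params = tuple(params)
    if magnitude < 0:
        raise ValueError("magnitude is a nonnegative number of sigmas")
    if pulses is not None:
        offsets = {p: (signs[p] * magnitude,) for p in params}
        return DisturbanceProfile(offsets, direction, tuple(pulses))
    if subphases is None or n_subphases is None:
        raise ValueError("subphases and n_subphases required for non-pulse profiles")
    sub = set(subphases)
    if any(i < 0 or i >= n_subphases for i in sub):
        raise IndexError(f"subphase index outside 0..{n_subphases - 1}")
    offsets = {
        p: tuple(signs[p] * magnitude if i in sub else 0.0 for i in range(n_subphases))
        for p in params
    }
    return DisturbanceProfile(offsets, direction, None)


def _offset_phase(phase: Phase, deltas: Mapping[str, float]) -> Phase:
    """Apply absolute setpoint deltas to one phase, clamping at zero."""
    new = {"T_in_set": phase.T_in_set, "F_air_set": phase.F_air_set,
           "F_spray_set": phase.F_spray_set}
    key = {"T_in": "T_in_set", "F_air": "F_air_set", "F_spray": "F_spray_set"}
    for param, d in deltas.items():
        k = key[param]
        v = new[k] + d
        if v < 0.0 and k != "T_in_set":
            log.warning("clamping %s of phase %r at 0 (requested %.4g)", k, phase.name, v)
            v = 0.0
        new[k] = v
    return replace(phase, **new)


def apply_disturbance(
    recipe: Recipe, profile: DisturbanceProfile, sigmas: ParameterStdDevs
) -> Recipe:
    """Return a new recipe with the profile's offsets added to the setpoints.

    Per-subphase offsets apply to the corresponding spray subphase.  Pulse
    profiles split the spray subphases at pulse boundaries and apply the
    offsets only inside the windows, preserving total phase durations.
    Setpoints driven negative are clamped at zero with a logged warning.
    """
    spray_idx = recipe.spray_indices
    if profile.pulses is None:
        n_sub = len(spray_idx)
        for param, offs in profile.offsets.items():
            if len(offs) not in (n_sub,):
                raise IndexError(
                    f"profile offsets for {param} reference {len(offs)} subphases, "
                    f"recipe has {n_sub}"
                )
        phases = list(recipe.phases)
        for j, i in enumerate(spray_idx):
            deltas = {
                param: offs[j] * sigmas.of(param)
                for param, offs in profile.offsets.items()
                if offs[j] != 0.0
            }
            if deltas:
                phases[i] = _offset_phase(phases[i], deltas)
        return replace(recipe, phases=tuple(phases))

    # pulse mode: uniform offset per parameter inside the windows
    deltas = {}
    for param, offs in profile.offsets.items():
        uniq = {o for o in offs}
        if len(uniq) != 1:
            raise RecipeValidationError("pulse profiles need one uniform offset per parameter")
        deltas[param] = offs[0] * sigmas.of(param)
    s0, s1 = recipe.spray_window()
    span = s1 - s0
    cuts = {0.0, span}
    for start, dur in profile.pulses:
        if start + dur > span + 1e-9:
            raise IndexError("pulse window extends beyond the spray stage")
        cuts.add(start)
        cuts.add(min(start + dur, span))
    in_pulse = lambda t: any(a - 1e-12 <= t < a + d - 1e-12 for a, d in profile.pulses)

    phases: list[Phase] = []
    t_abs = 0.0
    for p in recipe.phases:
        if p.kind != "spray":
            phases.append(p)
            t_abs += p.duration
            continue
        rel0, rel1 = t_abs - s0, t_abs - s0 + p.duration
        local = sorted({rel0, rel1} | {c for c in cuts if rel0 < c < rel1})
        for a, b in zip(local[:-1], local[1:]):
            seg = replace(p, duration=b - a, name=f"{p.name}[{a:.0f}-{b:.0f}s]")
            if in_pulse(a):
                seg = _offset_phase(seg, deltas)
            phases.append(seg)
        t_abs += p.duration
    return replace(recipe, phases=tuple(phases))


def select_recipe_by_humidity(
    recipes: Mapping[tuple[float, float], Recipe], x_in: float
) -> Recipe:
    """Pick the humidity-group recipe whose interval contains ``x_in`` [g/kg].

    ``recipes`` maps closed intervals (lo, hi) in g/kg to recipes, e.g. the
    three groups (1-3), (4-6), (7-10).  Raises ``ValueError`` when ``x_in``
    falls outside every group.
    """
    for (lo, hi), recipe in recipes.items():
        if lo <= x_in <= hi:
            return recipe
    ranges = sorted(recipes)
    raise ValueError(f"inlet humidity {x_in} g/kg outside all groups {ranges}")


# ---------------------------------------------------------------------------
# File I/O: YAML recipes, CSV batch samples


def _phase_to_dict(p: Phase, unit: float) -> dict:
    return {
        "name": p.name, "kind": p.kind, "duration": p.duration / unit,
        "T_in_set": p.T_in_set, "F_air_set": p.F_air_set,
        "F_spray_set": p.F_spray_set, "x_in": p.x_in,
    }


def read_recipe(path) -> Recipe:
    """Read a recipe from its YAML schema (see the package README).

    Durations may be declared in minutes via ``time_unit: min``; they are
    converted to seconds on read.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise RecipeValidationError(f"{path}: recipe file must be a mapping")
    unit_name = raw.get("time_unit", "s")
    if unit_name not in ("s", "min"):
        raise RecipeValidationError(f"{path}: time_unit must be 's' or 'min'")
    unit = 60.0 if unit_name == "min" else 1.0
    try:
        phases = tuple(
            Phase(
                name=str(p["name"]), kind=str(p["kind"]),
                duration=float(p["duration"]) * unit,
                T_in_set=float(p["T_in_set"]), F_air_set=float(p["F_air_set"]),
                F_spray_set=float(p.get("F_spray_set", 0.0)),
                x_in=float(p.get("x_in", 0.005)),
            )
            for p in raw["phases"]
        )
        return Recipe(
            phases=phases,
            m_solids_0=float(raw["m_solids_0"]),
            lod_0=float(raw.get("lod_0", 2.0)),
            w_s=float(raw.get("w_s", 0.08)),
            T_spray=float(raw.get("T_spray", 25.0)),
            T_bed_0=float(raw.get("T_bed_0", 22.0)),
            T_air_0=float(raw.get("T_air_0", 22.0)),
            T_wall_0=float(raw.get("T_wall_0", 22.0)),
            name=str(raw.get("name", "recipe")),
        )
    except KeyError as exc:
        raise RecipeValidationError(f"{path}: missing required field {exc}") from exc


def write_recipe(path, recipe: Recipe) -> None:
    """Write a recipe in the YAML schema read by :func:`read_recipe` (seconds)."""
    doc = {
        "name": recipe.name,
        "time_unit": "s",
        "m_solids_0": recipe.m_solids_0,
        "lod_0": recipe.lod_0,
        "w_s": recipe.w_s,
        "T_spray": recipe.T_spray,
        "T_bed_0": recipe.T_bed_0,
        "T_air_0": recipe.T_air_0,
        "T_wall_0": recipe.T_wall_0,
        "phases": [_phase_to_dict(p, 1.0) for p in recipe.phases],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_batch_samples(path) -> list[LODSample]:
    """Read LOD samples from a CSV with header ``t_min,lod_pct`` (minutes)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"t_min", "lod_pct"} - set(reader.fieldnames):
            raise RecipeValidationError(f"{path}: expected columns t_min,lod_pct")
        for row in reader:
            out.append(LODSample(t=float(row["t_min"]) * 60.0, lod=float(row["lod_pct"])))
    return out


def write_batch_samples(path, samples: Iterable[LODSample]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_min", "lod_pct"])
        for s in samples:
            writer.writerow([f"{s.t / 60.0:.6g}", f"{s.lod:.6g}"])
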