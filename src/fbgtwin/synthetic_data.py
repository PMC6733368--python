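"""Synthetic campaign generator: recipes, equipment tables and noisy batches.

No public granulation batch data exists, so fixtures are produced by the
twin itself from known ground-truth parameters: multi-phase recipes at
pilot (~60 kg) and commercial (~216 kg) scale, wet/target/dry process
conditions realized by +/-10% spray-rate scaling at constant total binder,
and batch records whose LOD samples carry measurement noise and
sampling-time jitter — the two error sources that dominate real records.

Ground-truth parameter defaults (theta_p = 12 mm effective size,
theta_e = 5 LOD%, alpha = 1) are fixture choices, not measured values.
theta_p is the model's lumped "effective" transfer size: it is far larger
than a physical granule because it absorbs the small wetted/active
fraction of the idealized monodisperse-sphere surface area.  It is set so
bed-side mass-transfer resistance is comparable to the air-side removal
capacity — the regime in which both parameters leave a visible signature
on the LOD trace and calibration is a meaningful, well-conditioned
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .recipe_model import (
    BatchRecord,
    DesignSpace,
    LODSample,
    ParameterStdDevs,
    Phase,
    Recipe,
    apply_disturbance,
    make_profile,
)
from .simulator import ModelParameters, simulate
from .thermo import EquipmentProperties, MaterialProperties

__all__ = [
    "SyntheticCampaign",
    "default_true_params",
    "default_material_properties",
    "equipment_properties",
    "default_sigmas",
    "make_recipe",
    "make_batch",
    "make_campaign",
    "make_product_archetype",
]

#: Linear scale factor between the pilot (60 kg) and commercial (216 kg) units.
COMMERCIAL_SCALE = 3.6

#: Default sampling plan: fraction of each stage at which a sample is pulled.
PREMIX_FRACS = (0.45, 0.9)
SPRAY_FRACS = (0.5,) * 5  # midpoint of each of the five spray subphases
DRY_FRACS = (0.2, 0.45, 0.7, 0.95)


def default_true_params() -> ModelParameters:
    """Fixture ground truth: 12 mm effective size, 5 LOD% efficiency scale."""
    return ModelParameters(theta_p=12e-3, theta_e=5.0)


def default_material_properties() -> MaterialProperties:
    return MaterialProperties()


def equipment_properties(scale: str = "pilot") -> EquipmentProperties:
    """Lumped equipment table for the pilot or commercial granulator.

    Commercial values scale the pilot chamber linearly in volume/flow and
    by the 2/3 power in wall/exchange areas, keeping the superficial air
    velocity comparable across scales.
    """
    if scale == "pilot":
        return EquipmentProperties()
    if scale == "commercial":
        s = COMMERCIAL_SCALE
        a = s ** (2.0 / 3.0)
        return EquipmentProperties(
            m_air=1.8 * s, V_chamber=1.5 * s, m_wall=400.0 * a * 1.3,
            UA_bed_wall=15.0 * a, UA_bed_air=500.0 * s, UA_air_wall=50.0 * a,
            UA_wall_env=20.0 * a, A_cross=0.5 * s,
        )
    raise ValueError(f"unknown scale {scale!r}")


def default_sigmas(scale: str = "pilot") -> ParameterStdDevs:
    """Typical per-parameter standard deviations of the granulator controls."""
    s = 1.0 if scale == "pilot" else COMMERCIAL_SCALE
    return ParameterStdDevs(sigma_T_in=1.0, sigma_F_air=0.01 * s,
                            sigma_F_spray=4.0e-4 * s)


def make_recipe(scale: str = "pilot", condition: str = "target",
                seed: int | None = None) -> Recipe:
    """Standard fixture recipe: premix + 5 spray subphases + 2 dry subphases.

    Pilot charge 60 kg, commercial 216 kg with flows scaled linearly.
    ``condition`` shifts the spray rate by +/-10% at constant total binder
    solution (durations rescaled inversely): ``wet`` runs faster/shorter,
    ``dry`` slower/longer.  Deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    if scale not in ("pilot", "commercial"):
        raise ValueError(f"unknown scale {scale!r}")
    s = 1.0 if scale == "pilot" else COMMERCIAL_SCALE
    factor = {"wet": 1.1, "target": 1.0, "dry": 1.0 / 1.1}[condition]
    F_air_sp, F_air_dry = 0.35 * s, 0.40 * s
    F_spray = 0.010 * s * factor
    t_sub = 360.0 / factor
    phases = [Phase("premix", "premix", 300.0, 60.0, F_air_sp, 0.0)]
    phases += [
        Phase(f"spray{i + 1}", "spray", t_sub, 55.0, F_air_sp, F_spray)
        for i in range(5)
    ]
    phases += [
        Phase("dry1", "dry", 900.0, 70.0, F_air_dry, 0.0),
        Phase("dry2", "dry", 900.0, 70.0, F_air_dry, 0.0),
    ]
    return Recipe(
        phases=tuple(phases), m_solids_0=60.0 * s, lod_0=2.0, w_s=0.08,
        name=f"{scale}-{condition}",
    )


def sample_times_for(recipe: Recipe) -> np.ndarray:
    """Planned sampling times [s]: 2 premix, one per spray subphase, 4 dry."""
    starts = recipe.phase_start_times()
    times = []
    premix = [i for i, p in enumerate(recipe.phases) if p.kind == "premix"]
    if premix:
        i = premix[0]
        d = sum(recipe.phases[j].duration for j in premix)
        times += [starts[i] + f * d for f in PREMIX_FRACS]
    for j, i in enumerate(recipe.spray_indices):
        frac = SPRAY_FRACS[j % len(SPRAY_FRACS)]
        times.append(starts[i] + frac * recipe.phases[i].duration)
    dry = [i for i, p in enumerate(recipe.phases) if p.kind == "dry"]
    if dry:
        t0 = starts[dry[0]]
        d = sum(recipe.phases[j].duration for j in dry)
        times += [t0 + f * d for f in DRY_FRACS]
    return np.array(sorted(times))


def make_batch(
    recipe: Recipe,
    true_params: ModelParameters,
    noise_sd: float = 0.1,
    time_jitter_sd: float = 30.0,
    n_samples: int | None = None,
    seed: int = 0,
    label: str = "",
    props: MaterialProperties | None = None,
    equip: EquipmentProperties | None = None,
) -> BatchRecord:
    """Simulate a batch at the true parameters and emit noisy LOD samples.

    LOD values are read off the true trajectory at the *actual* sampling
    times, perturbed by Normal(0, ``noise_sd``) [LOD %] and floored at 0;
    the *recorded* times carry Normal(0, ``time_jitter_sd``) [s] jitter,
    mimicking imprecise time bookkeeping on the shop floor.
    """
    rng = np.random.default_rng(seed)
    traj = simulate(recipe, true_params, props, equip)
    if n_samples is None:
        times = sample_times_for(recipe)
    else:
        if n_samples < 3:
            raise ValueError("need at least 3 samples")
        times = np.linspace(0.06, 0.98, n_samples) * recipe.total_duration
    lods = traj.lod_at(times)
    lods = np.maximum(lods + rng.normal(0.0, noise_sd, size=len(times)), 0.0)
    recorded = np.clip(times + rng.normal(0.0, time_jitter_sd, size=len(times)),
                       0.0, recipe.total_duration)
    order = np.argsort(recorded, kind="stable")
    samples = tuple(
        LODSample(t=float(recorded[i]), lod=float(min(lods[i], 99.9)))
        for i in order
    )
    return BatchRecord(recipe=recipe, samples=samples, label=label,
                       scale=recipe.m_solids_0)


@dataclass(frozen=True)
class SyntheticCampaign:
    """A complete synthetic product campaign with known ground truth.

    Batches A (wet) and B (dry) form the training set, C (target) the
    pilot validation batch and D the commercial-scale verification batch,
    mirroring the train/validate/verify split of an industrial transfer.
    """

    true_params: ModelParameters
    recipes: dict[str, Recipe]
    batches: dict[str, BatchRecord]
    noise_sd: float
    time_jitter_sd: float
    seed: int
    sigmas: ParameterStdDevs = field(default_factory=default_sigmas)
    props: MaterialProperties = field(default_factory=MaterialProperties)
    equip_pilot: EquipmentProperties = field(default_factory=EquipmentProperties)
    equip_commercial: EquipmentProperties = field(
        default_factory=lambda: equipment_properties("commercial")
    )

    def equip_for(self, label: str) -> EquipmentProperties:
        return self.equip_commercial if label == "D" else self.equip_pilot


def make_campaign(
    noise_sd: float = 0.1,
    time_jitter_sd: float = 30.0,
    seed: int = 0,
    true_params: ModelParameters | None = None,
) -> SyntheticCampaign:
    """Generate the four-batch A/B/C/D campaign at one ground truth."""
    true_params = true_params or default_true_params()
    props = default_material_properties()
    eq_p = equipment_properties("pilot")
    eq_c = equipment_properties("commercial")
    recipes = {
        "A": make_recipe("pilot", "wet"),
        "B": make_recipe("pilot", "dry"),
        "C": make_recipe("pilot", "target"),
        "D": make_recipe("commercial", "target"),
    }
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=4)
    batches = {
        label: make_batch(
            recipes[label], true_params, noise_sd, time_jitter_sd,
            seed=int(subseeds[i]), label=label, props=props,
            equip=eq_c if label == "D" else eq_p,
        )
        for i, label in enumerate("ABCD")
    }
    return SyntheticCampaign(
        true_params=true_params, recipes=recipes, batches=batches,
        noise_sd=noise_sd, time_jitter_sd=time_jitter_sd, seed=seed,
        props=props, equip_pilot=eq_p, equip_commercial=eq_c,
    )


def _condition_lod_maxima(
    campaign: SyntheticCampaign, x_in: float
) -> dict[str, float]:
    out = {}
    for cond in ("wet", "target", "dry"):
        r = make_recipe("pilot", cond).with_humidity(x_in)
        out[cond] = simulate(r, campaign.true_params, campaign.props,
                             campaign.equip_pilot).lod_max
    return out


def make_product_archetype(
    kind: str, seed: int = 0, noise_sd: float = 0.1, time_jitter_sd: float = 30.0
) -> tuple[SyntheticCampaign, DesignSpace]:
    """Build the robust or sensitive product archetype.

    Both share the same recipes; they differ in evaporation regime and in
    how the maximum-LOD design space is set, mirroring the two industrial
    case studies:

    * ``robust``: default ground truth (large effective transfer size, so
      drying is partly bed-side-limited and only mildly humidity-coupled)
      with a design space spanning the maximum LOD reached under the
      extreme coordinated 2-sigma wet/dry full-spray deviations at the
      extreme (1 and 10 g/kg) inlet humidities, plus a 0.3 LOD% buffer —
      a wide space inside which every small-magnitude scenario stays.
    * ``sensitive``: a fine, well-wetted product (small effective size)
      whose evaporation is limited by the air's moisture-removal capacity
      and therefore strongly coupled to inlet humidity; its design space
      is exactly the wet/dry condition batch range at target humidity
      (5 g/kg), the textbook largest/smallest-batch-maximum definition.
      The humidity extremes then fall outside it even with zero
      deviation.
    """
    if kind == "sensitive":
        campaign = make_campaign(noise_sd, time_jitter_sd, seed,
                                 true_params=ModelParameters(2e-3, 5.0))
        maxima = _condition_lod_maxima(campaign, 0.005)
        ds = DesignSpace(maxima["dry"], maxima["wet"])
        return campaign, ds
    if kind != "robust":
        raise ValueError(f"unknown archetype {kind!r}")
    campaign = make_campaign(noise_sd, time_jitter_sd, seed)
    target = make_recipe("pilot", "target")
    lo, hi = np.inf, -np.inf
    for x_gkg in (1.0, 10.0):
        base = target.with_humidity(x_gkg / 1000.0)
        for direction in ("wet", "dry"):
            prof = make_profile(direction, 2.0, ("T_in", "F_air", "F_spray"),
                                subphases=range(5), n_subphases=5)
            r = apply_disturbance(base, prof, campaign.sigmas)
            m = simulate(r, campaign.true_params, campaign.props,
                         campaign.equip_pilot).lod_max
            lo, hi = min(lo, m), max(hi, m)
    return campaign, DesignSpace(lo - 0.3, hi + 0.3)
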