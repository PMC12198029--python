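"""Physics-informed synthetic PGT event generator.

Emulates the statistical structure of prompt gamma-ray timing data from a
cylindrical acrylic-glass phantom (15 cm diameter, 40 cm length) irradiated
with 162 or 225 MeV pencil beams, viewed by an uncollimated detector at a
130° backward angle whose axis crosses the beam at half the nominal proton
range:

* proton range from the Bragg–Kleeman relation R = α·E^p, calibrated so
  162 MeV protons stop after ≈15 cm of acrylic glass;
* prompt gamma emission depths along the track: mostly uniform, with a
  Gaussian bump at the end of range; an air cavity of thickness ΔR
  shortens the track to R − ΔR;
* event time = proton transit time to the emission depth (integrated from
  the relativistic velocity along the slowing-down curve) + gamma
  time-of-flight to the detector + Gaussian bunch/detector jitter + a
  slowly decaying bunch-phase drift, folded into one RF period;
* event energy drawn from discrete de-excitation lines (with single/double
  escape satellites) blurred by the detector resolution, plus an
  exponential continuum; an uncorrelated background component is uniform
  in time;
* detected counts are Poisson with mean proportional to the delivered
  protons and to the solid-angle factor of the (ΔR-dependent) emission
  depths.

Everything is reproducible from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .spectra import (
    DEFAULT_T_RF_NS,
    EventList,
    SpotMeta,
    ValidationError,
)

__all__ = [
    "GammaLine",
    "SimConfig",
    "StudyDesign",
    "proton_range",
    "transit_time_profile",
    "solid_angle_factor",
    "simulate_spot",
    "apply_phase_drift",
    "generate_study",
    "accumulate_spots",
]

_PROTON_MASS_MEV = 938.27208816
_C_CM_PER_NS = 29.9792458


@dataclass(frozen=True)
class GammaLine:
    """A discrete prompt gamma line: centre (MeV), relative yield, and
    whether single/double escape satellites accompany it."""

    energy_MeV: float
    rel_yield: float
    escapes: bool = False


#: Default line catalogue: annihilation 511 keV, 10B* 718 keV, 11C* ~2 MeV,
#: 12C* 4.44 MeV (+escapes) and 16O* 6.13 MeV (+escapes).  Yields populate
#: every analysis window.
DEFAULT_LINES: tuple[GammaLine, ...] = (
    GammaLine(0.511, 0.15),
    GammaLine(0.718, 0.05),
    GammaLine(2.000, 0.10),
    GammaLine(4.440, 0.45, escapes=True),
    GammaLine(6.130, 0.25, escapes=True),
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic detector/beam model.

    Units: energies MeV, lengths cm (cavities mm where noted), times ns.
    ``events_per_1e9_protons`` is the expected number of detected events
    for a ΔR = 0 spot delivering 1e9 protons.
    """

    beam_energy: float = 162.0
    range_alpha: float = 15.0 / 162.0**1.77  # cm · MeV^-p, R(162 MeV) = 15 cm
    range_p: float = 1.77
    phantom_diameter_cm: float = 15.0
    phantom_length_cm: float = 40.0
    detector_angle_deg: float = 130.0
    detector_distance_cm: float = 30.0
    sigma_bunch_ns: float = 0.30
    sigma_detector_ns: float = 0.15
    lines: tuple[GammaLine, ...] = DEFAULT_LINES
    escape_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)  # full, SE, DE
    continuum_fraction: float = 0.30
    continuum_decay_MeV: float = 1.5
    background_fraction: float = 0.25
    background_fraction_high_energy: float = 0.35  # elevated neutron background
    high_energy_threshold_MeV: float = 200.0
    resolution_fwhm_at_1MeV: float = 0.04  # relative FWHM at 1 MeV, ∝ 1/sqrt(E)
    events_per_1e9_protons: float = 2e4
    bump_fraction: float = 0.15
    bump_sigma_cm: float = 0.5
    time_offset_ns: float = 3.0
    phase_drift_amplitude_ns: float = 0.5
    phase_drift_tau_spots: float = 10.0
    phase_drift_omega: float = 0.6
    t_rf_ns: float = DEFAULT_T_RF_NS
    energy_min_MeV: float = 0.1
    use_solid_angle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("continuum_fraction", "background_fraction", "bump_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.sigma_bunch_ns <= 0 or self.sigma_detector_ns <= 0:
            raise ValidationError("time spreads must be positive")
        if self.range_alpha <= 0 or self.range_p <= 0:
            raise ValidationError("Bragg–Kleeman coefficients must be positive")

    @property
    def sigma_time_ns(self) -> float:
        return float(np.hypot(self.sigma_bunch_ns, self.sigma_detector_ns))

    def effective_background_fraction(self, beam_energy: float) -> float:
        if beam_energy >= self.high_energy_threshold_MeV:
            return self.background_fraction_high_energy
        return self.background_fraction


@dataclass(frozen=True)
class StudyDesign:
    """Spot bookkeeping of one measurement campaign.

    Static measurements deliver ``static_spots`` spots per (energy, cavity);
    the first ``static_exclude`` are excluded (bunch-phase oscillation), the
    next ``static_train`` train, the last ``static_test`` test.  Scanned
    layers are emulated by their analysed central spots only and are
    test-only.
    """

    energies: tuple[float, ...] = (162.0, 225.0)
    cavities_mm: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    static_spots: int = 100
    static_exclude: int = 30
    static_train: int = 50
    static_test: int = 20
    protons_static: float = 1e9
    scanned_layers: int = 22
    scanned_per_layer: int = 5
    protons_scanned: float = 1e8
    include_scanned: bool = True
    accum_layers: int = 8

    def __post_init__(self) -> None:
        if self.static_exclude + self.static_train + self.static_test != self.static_spots:
            raise ValidationError(
                "static split sizes must sum to static_spots: "
                f"{self.static_exclude}+{self.static_train}+{self.static_test}"
                f" != {self.static_spots}"
            )


# ---------------------------------------------------------------------------
# proton transport closures


def proton_range(beam_energy: float, config: SimConfig) -> float:
    """Bragg–Kleeman range R = α·E^p in cm of acrylic glass."""
    if not beam_energy > 0:
        raise ValidationError(f"beam energy must be positive, got {beam_energy}")
    return config.range_alpha * beam_energy**config.range_p


def _velocity_cm_per_ns(kinetic_MeV: np.ndarray) -> np.ndarray:
    gamma = 1.0 + np.asarray(kinetic_MeV) / _PROTON_MASS_MEV
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    return beta * _C_CM_PER_NS


@lru_cache(maxsize=64)
def _transit_profile_cached(alpha: float, p: float, beam_energy: float, n: int = 2001):
    """Depth grid and cumulative transit time over the full range R(E)."""
    r0 = alpha * beam_energy**p
    z = np.linspace(0.0, r0, n)
    residual = np.maximum(r0 - z, 1e-4)  # floor keeps 1/v integrable at track end
    kinetic = (residual / alpha) ** (1.0 / p)
    t = cumulative_trapezoid(1.0 / _velocity_cm_per_ns(kinetic), z, initial=0.0)
    return z, t


def transit_time_profile(config: SimConfig, beam_energy: float | None = None):
    """(depth grid cm, transit time ns) along the slowing-down curve."""
    e = config.beam_energy if beam_energy is None else beam_energy
    if not e > 0:
        raise ValidationError(f"beam energy must be positive, got {e}")
    return _transit_profile_cached(config.range_alpha, config.range_p, float(e))


def _detector_position(config: SimConfig, beam_energy: float) -> tuple[float, float]:
    """(x, z) of the detector; beam runs along +z from the phantom entrance."""
    aim_z = 0.5 * proton_range(beam_energy, config)
    theta = np.deg2rad(config.detector_angle_deg)
    return (
        config.detector_distance_cm * float(np.sin(theta)),
        aim_z + config.detector_distance_cm * float(np.cos(theta)),
    )


def _distance_to_detector(z: np.ndarray, config: SimConfig, beam_energy: float) -> np.ndarray:
    det_x, det_z = _detector_position(config, beam_energy)
    return np.hypot(np.asarray(z) - det_z, det_x)


def _track_length(config: SimConfig, beam_energy: float, cavity_mm: float) -> float:
    length = proton_range(beam_energy, config) - cavity_mm / 10.0
    if length <= 0:
        raise ValidationError(
            f"cavity {cavity_mm} mm consumes the whole range at {beam_energy} MeV"
        )
    return length


def solid_angle_factor(config: SimConfig, beam_energy: float, cavity_mm: float) -> float:
    """Mean 1/d² over emission depths, normalised to the ΔR = 0 track."""
    if not config.use_solid_angle:
        return 1.0

    def mean_inv_sq(length: float) -> float:
        z = np.linspace(0.0, length, 501)
        return float(np.mean(_distance_to_detector(z, config, beam_energy) ** -2))

    ref = mean_inv_sq(_track_length(config, beam_energy, 0.0))
    return mean_inv_sq(_track_length(config, beam_energy, cavity_mm)) / ref


# ---------------------------------------------------------------------------
# event sampling


def _line_components(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expand the line catalogue into (energies, yields) incl. escape peaks."""
    full, se, de = config.escape_fractions
    energies, yields = [], []
    for line in config.lines:
        if line.escapes:
            for frac, shift in ((full, 0.0), (se, 0.511), (de, 1.022)):
                energies.append(line.energy_MeV - shift)
                yields.append(line.rel_yield * frac)
        else:
            energies.append(line.energy_MeV)
            yields.append(line.rel_yield)
    e = np.array(energies)
    y = np.array(yields)
    return e, y / y.sum()


def _sample_energies(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Line + continuum energy sampling with resolution blur."""
    is_continuum = rng.random(n) < config.continuum_fraction
    energies = np.empty(n)
    n_cont = int(is_continuum.sum())
    energies[is_continuum] = config.energy_min_MeV + rng.exponential(
        config.continuum_decay_MeV, n_cont
    )
    centres, weights = _line_components(config)
    choice = rng.choice(centres.size, size=n - n_cont, p=weights)
    line_e = centres[choice]
    # relative FWHM ∝ 1/sqrt(E)  =>  absolute sigma = f1·sqrt(E)/2.355
    sigma = config.resolution_fwhm_at_1MeV * np.sqrt(line_e) / 2.3548200450309493
    energies[~is_continuum] = line_e + rng.normal(0.0, 1.0, line_e.size) * sigma
    return np.maximum(energies, 1e-3)


def _sample_background_energies(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    return config.energy_min_MeV + rng.exponential(config.continuum_decay_MeV, n)


def _sample_depths(rng: np.random.Generator, n: int, length: float, config: SimConfig) -> np.ndarray:
    """Uniform-track emission with a Gaussian end-of-range bump."""
    bump = rng.random(n) < config.bump_fraction
    z = np.empty(n)
    z[~bump] = rng.uniform(0.0, length, int((~bump).sum()))
    z[bump] = rng.normal(length, config.bump_sigma_cm, int(bump.sum()))
    return np.clip(z, 0.0, length)


def simulate_spot(config: SimConfig, meta: SpotMeta) -> EventList:
    """Generate the detected event list of one proton spot.

    The event count is Poisson with mean
    ``events_per_1e9_protons · (n_protons/1e9) · solid_angle_factor(ΔR)``.
    Reproducible from ``meta.seed`` (falling back to ``config.seed``).
    """
    seed = meta.seed if meta.seed is not None else config.seed
    rng = np.random.default_rng(seed)
    beam_energy = meta.beam_energy
    lam = (
        config.events_per_1e9_protons
        * (meta.n_protons / 1e9)
        * solid_angle_factor(config, beam_energy, meta.cavity_mm)
    )
    n = int(rng.poisson(lam))
    bg_fraction = config.effective_background_fraction(beam_energy)
    is_bg = rng.random(n) < bg_fraction
    n_bg = int(is_bg.sum())
    n_sig = n - n_bg

    times = np.empty(n)
    energies = np.empty(n)

    # signal: transit + time of flight + jitter + constant offset
    length = _track_length(config, beam_energy, meta.cavity_mm)
    z = _sample_depths(rng, n_sig, length, config)
    grid_z, grid_t = transit_time_profile(config, beam_energy)
    transit = np.interp(z, grid_z, grid_t)
    tof = _distance_to_detector(z, config, beam_energy) / _C_CM_PER_NS
    jitter = rng.normal(0.0, config.sigma_time_ns, n_sig)
    times[~is_bg] = transit + tof + jitter + config.time_offset_ns
    energies[~is_bg] = _sample_energies(rng, n_sig, config)

    # background: uniform in time, exponential in energy
    times[is_bg] = rng.uniform(0.0, config.t_rf_ns, n_bg)
    energies[is_bg] = _sample_background_energies(rng, n_bg, config)

    times = np.mod(times, config.t_rf_ns)
    return EventList(meta=meta, energy_MeV=energies, time_ns=times, t_rf_ns=config.t_rf_ns)


def apply_phase_drift(events: EventList, spot_index: int, config: SimConfig) -> EventList:
    """Add the deterministic bunch-phase offset of spot ``spot_index``.

    offset = A · exp(−i/τ) · cos(ω·i), folded mod T_RF.  The offset decays
    to zero for large spot indices, emulating the phase oscillation that
    motivates excluding the first spots of a static measurement.
    """
    if spot_index < 0:
        raise ValidationError(f"spot_index must be >= 0, got {spot_index}")
    amp = config.phase_drift_amplitude_ns
    if amp == 0.0:
        return events
    offset = (
        amp
        * np.exp(-spot_index / config.phase_drift_tau_spots)
        * np.cos(config.phase_drift_omega * spot_index)
    )
    times = np.mod(events.time_ns + offset, events.t_rf_ns)
    return EventList(meta=events.meta, energy_MeV=events.energy_MeV, time_ns=times, t_rf_ns=events.t_rf_ns)


def phase_drift_offset(spot_index: int, config: SimConfig) -> float:
    """The deterministic phase offset (ns) applied to spot ``spot_index``."""
    return float(
        config.phase_drift_amplitude_ns
        * np.exp(-spot_index / config.phase_drift_tau_spots)
        * np.cos(config.phase_drift_omega * spot_index)
    )


# ---------------------------------------------------------------------------
# study generation


def _spot_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-spot seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def generate_study(design: StudyDesign, config: SimConfig) -> list[EventList]:
    """Generate every spot of a measurement campaign with split labels.

    Static spots per (energy, cavity): exclude / train / test in delivery
    order, with the bunch-phase drift applied by spot index.  Scanned spots
    (the analysed central spots of each layer) are test-only.
    """
    spots: list[EventList] = []
    n_static = len(design.energies) * len(design.cavities_mm) * design.static_spots
    n_scanned = (
        len(design.energies)
        * len(design.cavities_mm)
        * design.scanned_layers
        * design.scanned_per_layer
        if design.include_scanned
        else 0
    )
    seeds = iter(_spot_seeds(config.seed, n_static + n_scanned))

    for energy in design.energies:
        cfg = replace(config, beam_energy=energy)
        for cavity in design.cavities_mm:
            for i in range(design.static_spots):
                if i < design.static_exclude:
                    split = "exclude"
                elif i < design.static_exclude + design.static_train:
                    split = "train"
                else:
                    split = "test"
                meta = SpotMeta(
                    spot_id=f"static_E{energy:g}_dR{cavity:g}_s{i:03d}",
                    beam_energy=energy,
                    mode="static",
                    cavity_mm=cavity,
                    n_protons=design.protons_static,
                    seed=next(seeds),
                    split=split,
                    dataset="static",
                )
                spots.append(apply_phase_drift(simulate_spot(cfg, meta), i, cfg))
            if design.include_scanned:
                for layer in range(design.scanned_layers):
                    for j in range(design.scanned_per_layer):
                        index = layer * design.scanned_per_layer + j
                        meta = SpotMeta(
                            spot_id=f"scanned_E{energy:g}_dR{cavity:g}_L{layer:02d}_s{j}",
                            beam_energy=energy,
                            mode="scanned",
                            cavity_mm=cavity,
                            layer_index=layer,
                            n_protons=design.protons_scanned,
                            seed=next(seeds),
                            split="test",
                            dataset="scanned",
                        )
                        spots.append(apply_phase_drift(simulate_spot(cfg, meta), index, cfg))
    return spots


def accumulate_spots(spots: list[EventList]) -> EventList:
    """Concatenate spots sharing (beam energy, cavity) into one event list.

    Emulates accumulating scanned spots over consecutive layers to reach
    static-like counting statistics; protons are summed and member spot ids
    recorded as provenance.
    """
    if not spots:
        raise ValidationError("cannot accumulate an empty spot list")
    first = spots[0].meta
    for s in spots[1:]:
        if s.meta.beam_energy != first.beam_energy or s.meta.cavity_mm != first.cavity_mm:
            raise ValidationError(
                "accumulate_spots requires identical beam energy and cavity; got "
                f"({s.meta.beam_energy}, {s.meta.cavity_mm}) vs "
                f"({first.beam_energy}, {first.cavity_mm})"
            )
    if len(spots) == 1:
        return spots[0]
    members = tuple(s.meta.spot_id for s in spots)
    meta = SpotMeta(
        spot_id="+".join(members[:1]) + f"+{len(members) - 1}more",
        beam_energy=first.beam_energy,
        mode=first.mode,
        cavity_mm=first.cavity_mm,
        layer_index=first.layer_index,
        n_protons=float(sum(s.meta.n_protons for s in spots)),
        seed=first.seed,
        split=first.split,
        dataset=first.dataset,
        members=members,
    )
    return EventList(
        meta=meta,
        energy_MeV=np.concatenate([s.energy_MeV for s in spots]),
        time_ns=np.concatenate([s.time_ns for s in spots]),
        t_rf_ns=spots[0].t_rf_ns,
    )


def accumulate_scanned_layers(spots: list[EventList], accum_layers: int) -> list[EventList]:
    """Group scanned spots of equal (energy, cavity, in-layer position) over
    blocks of ``accum_layers`` consecutive layers and accumulate each block."""
    groups: dict[tuple, list[EventList]] = {}
    for s in spots:
        if s.meta.dataset != "scanned":
            continue
        pos = s.meta.spot_id.rsplit("_s", 1)[-1]
        key = (s.meta.beam_energy, s.meta.cavity_mm, pos, s.meta.layer_index // accum_layers)
        groups.setdefault(key, []).append(s)
    out = []
    for key in sorted(groups, key=str):
        members = groups[key]
        if len(members) < accum_layers:
            continue  # incomplete trailing block
        acc = accumulate_spots(members)
        acc.meta = replace(acc.meta, dataset=f"scanned_accum{accum_layers}")
        out.append(acc)
    return out
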