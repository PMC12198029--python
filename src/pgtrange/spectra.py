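"""Event lists and binned time–energy spectra for prompt gamma-ray timing.

A PGT detector records, for every prompt gamma ray, its deposited energy
(MeV) and its trigger time relative to the accelerator radio-frequency
period (ns).  The analysis works on 2D histograms of these event lists:
counts over a (time bins × energy bins) grid, one spectrum per proton spot.

Conventions fixed here and used project-wide:

* time bin width is 1.06/230 ns (five analysis segments of 230 bins span
  1.06 ns each); the RF period is a whole number of bins, by default
  2040 bins ≈ 9.4017 ns;
* all binning is half-open ``[lo, hi)`` with the lower edge inclusive;
  events at or beyond the global upper energy edge are excluded and
  reported in a discard tally;
* energy windows follow the nuclear-line table (positron annihilation,
  10B, 11C, 12C+11B, 16O) with escape peaks included in the ranges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import h5py
import numpy as np

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "TIME_BIN_WIDTH_NS",
    "DEFAULT_N_TIME_BINS",
    "DEFAULT_T_RF_NS",
    "GammaEvent",
    "SpotMeta",
    "EventList",
    "BinningSpec",
    "Spectrum2D",
    "EnergyWindow",
    "TABLE1_WINDOWS",
    "TimeSegment",
    "time_segments",
    "bin_events",
    "project_time",
    "project_energy",
    "restrict_energy",
    "segment_time",
    "time_centers",
    "read_events",
    "write_events",
    "read_spectrum",
    "write_spectrum",
]


class ConfigurationError(ValueError):
    """Invalid binning, windowing or pipeline configuration."""


class ValidationError(ValueError):
    """Data violating a domain invariant (e.g. negative gamma energy)."""


#: Width of one time bin: 230 bins span 1.06 ns.
TIME_BIN_WIDTH_NS: float = 1.06 / 230.0

#: Number of time bins in one RF period (nominal 9.4 ns period snapped to
#: a whole number of bins).
DEFAULT_N_TIME_BINS: int = int(round(9.4 / TIME_BIN_WIDTH_NS))

#: The RF period actually used: an exact multiple of the bin width.
DEFAULT_T_RF_NS: float = DEFAULT_N_TIME_BINS * TIME_BIN_WIDTH_NS

#: Number of bins per analysis time segment.
SEGMENT_BINS: int = 230

#: Number of analysis time segments.
N_SEGMENTS: int = 5


class GammaEvent(NamedTuple):
    """One detected prompt gamma ray."""

    energy_MeV: float
    time_ns: float


@dataclass(frozen=True)
class SpotMeta:
    """Metadata of one proton spot (or an accumulation of spots).

    ``dataset`` distinguishes evaluation datasets (``static``, ``scanned``,
    ``scanned_accum8``); it defaults to ``mode``.  ``split`` carries the
    train/test/exclude label assigned by the study design.  ``members``
    records provenance when spots are accumulated.
    """

    spot_id: str
    beam_energy: float
    mode: str
    cavity_mm: float
    layer_index: int = 0
    n_protons: float = 1e9
    seed: int | None = None
    split: str | None = None
    dataset: str | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("static", "scanned"):
            raise ValidationError(f"mode must be 'static' or 'scanned', got {self.mode!r}")
        if not self.cavity_mm >= 0:
            raise ValidationError(f"cavity_mm must be >= 0, got {self.cavity_mm}")
        if not self.n_protons > 0:
            raise ValidationError(f"n_protons must be > 0, got {self.n_protons}")
        if self.layer_index < 0:
            raise ValidationError(f"layer_index must be >= 0, got {self.layer_index}")
        if self.dataset is None:
            object.__setattr__(self, "dataset", self.mode)


@dataclass
class EventList:
    """Detected gamma events of one spot, as flat arrays.

    Times live in ``[0, t_rf_ns)``; energies are finite and positive.
    """

    meta: SpotMeta
    energy_MeV: np.ndarray
    time_ns: np.ndarray
    t_rf_ns: float = DEFAULT_T_RF_NS

    def __post_init__(self) -> None:
        self.energy_MeV = np.asarray(self.energy_MeV, dtype=float)
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        if self.energy_MeV.shape != self.time_ns.shape or self.energy_MeV.ndim != 1:
            raise ValidationError("energy_MeV and time_ns must be 1D arrays of equal length")
        if self.energy_MeV.size:
            if not np.all(np.isfinite(self.energy_MeV)) or not np.all(self.energy_MeV > 0):
                raise ValidationError("energy_MeV must be finite and positive")
            if not np.all((self.time_ns >= 0) & (self.time_ns < self.t_rf_ns)):
                raise ValidationError(f"time_ns must lie in [0, {self.t_rf_ns})")

    def __len__(self) -> int:
        return int(self.energy_MeV.size)

    @property
    def events(self) -> list[GammaEvent]:
        return [GammaEvent(float(e), float(t)) for e, t in zip(self.energy_MeV, self.time_ns)]


@dataclass(frozen=True)
class BinningSpec:
    """Binning of a 2D time–energy spectrum.

    For full-period spectra ``n_time_bins * time_bin_width_ns`` equals the
    RF period; spectra cropped in time or energy (segments, windows) reuse
    the same class with reduced extents.
    """

    time_bin_width_ns: float = TIME_BIN_WIDTH_NS
    n_time_bins: int = DEFAULT_N_TIME_BINS
    energy_bin_width_MeV: float = 0.025
    energy_min_MeV: float = 0.1
    energy_max_MeV: float = 8.0

    def __post_init__(self) -> None:
        if self.time_bin_width_ns <= 0 or self.energy_bin_width_MeV <= 0:
            raise ConfigurationError("bin widths must be positive")
        if self.n_time_bins < 1:
            raise ConfigurationError("n_time_bins must be >= 1")
        if not self.energy_max_MeV > self.energy_min_MeV:
            raise ConfigurationError("energy_max_MeV must exceed energy_min_MeV")
        n = (self.energy_max_MeV - self.energy_min_MeV) / self.energy_bin_width_MeV
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                "energy range must be an integer number of energy bins"
            )

    @property
    def t_rf_ns(self) -> float:
        return self.n_time_bins * self.time_bin_width_ns

    @property
    def n_energy_bins(self) -> int:
        return int(round((self.energy_max_MeV - self.energy_min_MeV) / self.energy_bin_width_MeV))

    @property
    def time_edges_ns(self) -> np.ndarray:
        return np.arange(self.n_time_bins + 1) * self.time_bin_width_ns

    @property
    def energy_edges_MeV(self) -> np.ndarray:
        return self.energy_min_MeV + np.arange(self.n_energy_bins + 1) * self.energy_bin_width_MeV


@dataclass
class Spectrum2D:
    """Binned counts over (time bins × energy bins) with provenance.

    ``time_offset_bins`` locates cropped time axes (segments) within the
    full RF period so that physical time centres stay meaningful.
    """

    meta: SpotMeta
    counts: np.ndarray
    binning: BinningSpec
    corrected_flags: tuple[str, ...] = ()
    time_offset_bins: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (self.binning.n_time_bins, self.binning.n_energy_bins)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match binning {expected}"
            )
        if self.counts.size and np.min(self.counts) < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class EnergyWindow:
    """Named gamma-line energy region, half-open ``[e_min, e_max)`` in MeV."""

    name: str
    e_min: float
    e_max: float

    def __post_init__(self) -> None:
        if not self.e_min < self.e_max:
            raise ConfigurationError(f"window {self.name}: e_min must be < e_max")


#: Nuclear-line energy regions (escape peaks included in the ranges):
#: positron annihilation, 10B, 11C, 12C+11B, 16O de-excitation lines.
TABLE1_WINDOWS: tuple[EnergyWindow, ...] = (
    EnergyWindow("511keV", 0.3, 0.6),
    EnergyWindow("B10", 0.6, 0.8),
    EnergyWindow("C11", 1.8, 2.1),
    EnergyWindow("C12_B11", 3.3, 4.6),
    EnergyWindow("O16", 5.0, 6.3),
)


@dataclass(frozen=True)
class TimeSegment:
    """Half-open bin-index range of one 230-bin analysis time segment."""

    index: int
    bin_start: int
    bin_stop: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_SEGMENTS:
            raise ConfigurationError("segment index must be in 0..4")
        if self.bin_stop - self.bin_start != SEGMENT_BINS:
            raise ConfigurationError("segments are exactly 230 bins wide")


def time_segments() -> tuple[TimeSegment, ...]:
    """The five contiguous 230-bin segments anchored at bin 0."""
    return tuple(
        TimeSegment(i, i * SEGMENT_BINS, (i + 1) * SEGMENT_BINS) for i in range(N_SEGMENTS)
    )


# ---------------------------------------------------------------------------
# histogramming


def bin_events(events: EventList, binning: BinningSpec) -> tuple[Spectrum2D, int]:
    """Histogram an event list onto the 2D time–energy grid.

    Returns ``(spectrum, n_discarded)`` where the tally counts events whose
    energy falls outside ``[energy_min, energy_max)``.  Times are folded
    into one RF period before binning.  Count conservation:
    ``spectrum.total + n_discarded == len(events)``.
    """
    b = binning
    t = np.mod(events.time_ns, b.t_rf_ns)
    e = events.energy_MeV
    ti = np.floor(t / b.time_bin_width_ns).astype(np.int64)
    # guard against float fold landing exactly on the upper period edge
    np.clip(ti, 0, b.n_time_bins - 1, out=ti)
    ei = np.floor((e - b.energy_min_MeV) / b.energy_bin_width_MeV).astype(np.int64)
    keep = (e >= b.energy_min_MeV) & (ei < b.n_energy_bins)
    n_discarded = int(e.size - keep.sum())
    counts = np.zeros((b.n_time_bins, b.n_energy_bins))
    np.add.at(counts, (ti[keep], ei[keep]), 1.0)
    return Spectrum2D(meta=events.meta, counts=counts, binning=b), n_discarded


def project_time(spec: Spectrum2D) -> np.ndarray:
    """1D time histogram: sum over energy bins (total preserved)."""
    return spec.counts.sum(axis=1)


def project_energy(spec: Spectrum2D) -> np.ndarray:
    """1D energy histogram: sum over time bins (total preserved)."""
    return spec.counts.sum(axis=0)


def time_centers(spec: Spectrum2D) -> np.ndarray:
    """Physical bin-centre times in ns, honouring any time-crop offset."""
    b = spec.binning
    return (spec.time_offset_bins + np.arange(b.n_time_bins) + 0.5) * b.time_bin_width_ns


def energy_centers(spec: Spectrum2D) -> np.ndarray:
    """Physical bin-centre energies in MeV."""
    b = spec.binning
    return b.energy_min_MeV + (np.arange(b.n_energy_bins) + 0.5) * b.energy_bin_width_MeV


def restrict_energy(spec: Spectrum2D, window: EnergyWindow) -> Spectrum2D:
    """Crop a spectrum to one energy window.

    Bins overlapping ``[e_min, e_max)`` are kept.  With the default 25 keV
    grid every catalogue window aligns exactly with bin edges, so the crop
    is edge-exact and the five windows partition their union.
    """
    b = spec.binning
    edges = b.energy_edges_MeV
    eps = 1e-9 * b.energy_bin_width_MeV  # edge-rounding guard
    mask = (edges[:-1] < window.e_max - eps) & (edges[1:] > window.e_min + eps)
    if not mask.any():
        raise ConfigurationError(
            f"energy window {window.name!r} [{window.e_min}, {window.e_max}) MeV is "
            f"disjoint from the spectrum domain [{b.energy_min_MeV}, {b.energy_max_MeV})"
        )
    idx = np.flatnonzero(mask)
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    new_binning = replace(
        b,
        energy_min_MeV=b.energy_min_MeV + lo * b.energy_bin_width_MeV,
        energy_max_MeV=b.energy_min_MeV + hi * b.energy_bin_width_MeV,
    )
    return Spectrum2D(
        meta=spec.meta,
        counts=spec.counts[:, lo:hi].copy(),
        binning=new_binning,
        corrected_flags=spec.corrected_flags + (f"window:{window.name}",),
        time_offset_bins=spec.time_offset_bins,
    )


def segment_time(spec: Spectrum2D) -> list[Spectrum2D]:
    """Split the time axis into the five 230-bin segments (anchored at bin 0).

    Requires at least 1150 time bins; bins beyond 5×230 are not part of any
    segment.
    """
    b = spec.binning
    if b.n_time_bins < N_SEGMENTS * SEGMENT_BINS:
        raise ConfigurationError(
            f"time segmentation needs >= {N_SEGMENTS * SEGMENT_BINS} time bins, "
            f"got {b.n_time_bins}"
        )
    out = []
    for seg in time_segments():
        new_binning = replace(b, n_time_bins=SEGMENT_BINS)
        out.append(
            Spectrum2D(
                meta=spec.meta,
                counts=spec.counts[seg.bin_start : seg.bin_stop].copy(),
                binning=new_binning,
                corrected_flags=spec.corrected_flags + (f"segment:{seg.index}",),
                time_offset_bins=spec.time_offset_bins + seg.bin_start,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O
#
# Event lists: delimited text with a '# key=value' metadata header.
# Spectra: HDF5 container with datasets counts / time_edges_ns /
# energy_edges_MeV and a 'meta' attribute group.

_META_FIELDS = (
    "spot_id",
    "beam_energy",
    "mode",
    "cavity_mm",
    "layer_index",
    "n_protons",
    "seed",
    "split",
    "dataset",
    "members",
)

_SCHEMA_VERSION = "1"


def _meta_to_items(meta: SpotMeta) -> list[tuple[str, str]]:
    items = [("schema", _SCHEMA_VERSION)]
    for name in _META_FIELDS:
        value = getattr(meta, name)
        if value is None:
            continue
        if name == "members":
            if not value:
                continue
            value = ";".join(value)
        items.append((name, str(value)))
    return items


def _meta_from_mapping(mapping: dict[str, str], path: str) -> SpotMeta:
    kwargs: dict[str, object] = {}
    try:
        kwargs["spot_id"] = mapping["spot_id"]
        kwargs["beam_energy"] = float(mapping["beam_energy"])
        kwargs["mode"] = mapping["mode"]
        kwargs["cavity_mm"] = float(mapping["cavity_mm"])
    except KeyError as exc:
        raise ValidationError(f"{path}: missing metadata field {exc.args[0]!r}") from exc
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed metadata value ({exc})") from exc
    for name, conv in (
        ("layer_index", int),
        ("n_protons", float),
        ("seed", int),
    ):
        if name in mapping:
            try:
                kwargs[name] = conv(mapping[name])
            except ValueError as exc:
                raise ValidationError(f"{path}: malformed field {name!r}") from exc
    for name in ("split", "dataset"):
        if name in mapping:
            kwargs[name] = mapping[name]
    if "members" in mapping:
        kwargs["members"] = tuple(m for m in mapping["members"].split(";") if m)
    try:
        return SpotMeta(**kwargs)  # type: ignore[arg-type]
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_events(path, events: EventList) -> None:
    """Write an event list as a text table with a metadata header."""
    with open(path, "w") as fh:
        for key, value in _meta_to_items(events.meta):
            fh.write(f"# {key}={value}\n")
        fh.write(f"# t_rf_ns={events.t_rf_ns!r}\n")
        fh.write("energy_MeV,time_ns\n")
        for e, t in zip(events.energy_MeV, events.time_ns):
            fh.write(f"{float(e)!r},{float(t)!r}\n")


def read_events(path) -> EventList:
    """Read an event list written by :func:`write_events`."""
    mapping: dict[str, str] = {}
    energies: list[float] = []
    times: list[float] = []
    saw_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ValidationError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, value = body.partition("=")
                mapping[key.strip()] = value.strip()
                continue
            if not saw_header:
                if line.replace(" ", "") != "energy_MeV,time_ns":
                    raise ValidationError(
                        f"{path}:{lineno}: expected column header 'energy_MeV,time_ns'"
                    )
                saw_header = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                energies.append(float(parts[0]))
                times.append(float(parts[1]))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed number ({exc})") from exc
    meta = _meta_from_mapping(mapping, str(path))
    t_rf = float(mapping.get("t_rf_ns", DEFAULT_T_RF_NS))
    try:
        return EventList(meta=meta, energy_MeV=np.array(energies), time_ns=np.array(times), t_rf_ns=t_rf)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_spectrum(path, spec: Spectrum2D) -> None:
    """Write a spectrum to an HDF5 container."""
    b = spec.binning
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=spec.counts)
        fh.create_dataset("time_edges_ns", data=b.time_edges_ns + spec.time_offset_bins * b.time_bin_width_ns)
        fh.create_dataset("energy_edges_MeV", data=b.energy_edges_MeV)
        grp = fh.create_group("meta")
        for key, value in _meta_to_items(spec.meta):
            grp.attrs[key] = value
        grp.attrs["corrected_flags"] = ";".join(spec.corrected_flags)
        grp.attrs["time_offset_bins"] = spec.time_offset_bins
        for name in dataclasses.fields(b):
            grp.attrs[f"binning.{name.name}"] = getattr(b, name.name)


def read_spectrum(path) -> Spectrum2D:
    """Read a spectrum written by :func:`write_spectrum`."""
    with h5py.File(path, "r") as fh:
        try:
            counts = fh["counts"][()]
        except KeyError as exc:
            raise ValidationError(f"{path}: missing dataset 'counts'") from exc
        grp = fh["meta"]
        attrs = {k: grp.attrs[k] for k in grp.attrs}
        mapping = {k: str(v) for k, v in attrs.items() if not k.startswith("binning.")}
        meta = _meta_from_mapping(mapping, str(path))
        try:
            binning = BinningSpec(
                time_bin_width_ns=float(attrs["binning.time_bin_width_ns"]),
                n_time_bins=int(attrs["binning.n_time_bins"]),
                energy_bin_width_MeV=float(attrs["binning.energy_bin_width_MeV"]),
                energy_min_MeV=float(attrs["binning.energy_min_MeV"]),
                energy_max_MeV=float(attrs["binning.energy_max_MeV"]),
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: missing binning attribute {exc.args[0]!r}") from exc
        flags = tuple(f for f in str(attrs.get("corrected_flags", "")).split(";") if f)
        return Spectrum2D(
            meta=meta,
            counts=counts,
            binning=binning,
            corrected_flags=flags,
            time_offset_bins=int(attrs.get("time_offset_bins", 0)),
        )
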