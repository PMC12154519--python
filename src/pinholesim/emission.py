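"""Lu-177 photon emission model and energy-window logic.

Lu-177 is a beta emitter whose imageable gammas sit at 112.95 keV (~6.2 per
100 decays) and 208.37 keV (~10.4 per 100 decays), with several weak lines.
Betas and bremsstrahlung are not transported: planar imaging with this camera
uses only the gamma peaks, selected by symmetric fractional energy windows
(e.g. +-10% about 113 keV, or the combined +-35% window about both peaks
spanning roughly 73-281 keV).

The default line table below uses standard nuclear-data (ENSDF/NuDat)
intensities; the study this models delegated the spectrum to a general-purpose
ion source, so the table is override-able both in code and from a two-column
CSV (``energy_keV,intensity``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmissionLine",
    "EmissionSpectrum",
    "EnergyWindow",
    "build_lu177_spectrum",
    "make_energy_window",
    "sample_emissions",
    "in_window",
    "spectrum_from_csv",
]


@dataclass(frozen=True)
class EmissionLine:
    """A discrete gamma line: energy in keV, intensity in photons per decay."""

    energy_kev: float
    intensity: float

    def __post_init__(self):
        if self.energy_kev <= 0:
            raise ValueError(f"line energy must be positive, got {self.energy_kev}")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError(
                f"line intensity must be in (0, 1], got {self.intensity}"
            )


@dataclass(frozen=True)
class EmissionSpectrum:
    """Ordered set of emission lines; lines are sorted by increasing energy."""

    lines: tuple[EmissionLine, ...]

    def __post_init__(self):
        if not self.lines:
            raise ValueError("spectrum needs at least one line")
        object.__setattr__(
            self, "lines", tuple(sorted(self.lines, key=lambda l: l.energy_kev))
        )

    @property
    def total_gamma_yield(self) -> float:
        """Expected photons emitted per decay (sum of line intensities)."""
        return float(sum(l.intensity for l in self.lines))

    @property
    def energies(self) -> np.ndarray:
        return np.array([l.energy_kev for l in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([l.intensity for l in self.lines])


# ENSDF/NuDat gamma intensities for Lu-177 (photons per decay).
_LU177_PRINCIPAL = (
    EmissionLine(112.95, 0.0617),
    EmissionLine(208.37, 0.1036),
)
_LU177_MINOR = (
    EmissionLine(71.64, 0.00154),
    EmissionLine(136.72, 0.00047),
    EmissionLine(249.67, 0.00201),
    EmissionLine(321.32, 0.00216),
)


def build_lu177_spectrum(
    overrides: Iterable[EmissionLine] | None = None,
    include_minor_lines: bool = True,
) -> EmissionSpectrum:
    """Default Lu-177 gamma spectrum, or an explicit replacement table.

    Parameters
    ----------
    overrides:
        If given, the returned spectrum contains exactly these lines.
    include_minor_lines:
        Keep the weak 71.6/136.7/249.7/321.3 keV lines (default).  They carry
        <0.6% of the photon yield but the 249.7 keV line falls inside the wide
        73-281 keV imaging window.
    """
    if overrides is not None:
        lines = tuple(overrides)
        if not lines:
            raise ValueError("override line table must not be empty")
        return EmissionSpectrum(lines)
    lines = _LU177_PRINCIPAL + (_LU177_MINOR if include_minor_lines else ())
    return EmissionSpectrum(lines)


def spectrum_from_csv(path: str | Path) -> EmissionSpectrum:
    """Load an override spectrum from a two-column CSV (energy_keV,intensity).

    A header row is permitted and detected by non-numeric content.
    """
    rows = []
    for raw in Path(path).read_text().splitlines():
        raw = raw.strip()
        if not raw:
            continue
        parts = raw.split(",")
        try:
            e, i = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if rows:
                raise ValueError(f"malformed spectrum row: {raw!r}")
            continue  # header
        rows.append(EmissionLine(e, i))
    return EmissionSpectrum(tuple(rows))


@dataclass(frozen=True)
class EnergyWindow:
    """A union of disjoint, inclusive [low, high] intervals in keV."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("window needs at least one interval")
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not a < b:
                raise ValueError(f"interval low must be < high, got ({a}, {b})")
        ivs = tuple(sorted(ivs))
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 <= b1:
                raise ValueError("intervals must be non-overlapping after union")
        object.__setattr__(self, "intervals", ivs)

    @property
    def low(self) -> float:
        return self.intervals[0][0]

    @property
    def high(self) -> float:
        return self.intervals[-1][1]

    def label(self) -> str:
        return "+".join(f"{a:g}-{b:g}keV" for a, b in self.intervals)


def make_energy_window(
    peaks: Sequence[float], half_width_fraction: float
) -> EnergyWindow:
    """Symmetric fractional window(s) about photopeaks, merged where they touch.

    ``make_energy_window([113, 208], 0.35)`` gives the single merged
    73.45-280.8 keV interval used for sensitivity measurements.
    """
    if len(peaks) == 0:
        raise ValueError("need at least one peak energy")
    if not (0.0 < half_width_fraction < 1.0):
        raise ValueError("half_width_fraction must be in (0, 1)")
    raw = sorted(
        (p * (1.0 - half_width_fraction), p * (1.0 + half_width_fraction))
        for p in peaks
    )
    merged: list[list[float]] = [list(raw[0])]
    for a, b in raw[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return EnergyWindow(tuple((a, b) for a, b in merged))


def in_window(energy_kev, window: EnergyWindow):
    """Vectorised inclusive membership test: is the energy in any interval?"""
    e = np.asarray(energy_kev, dtype=float)
    out = np.zeros(e.shape, dtype=bool)
    for a, b in window.intervals:
        out |= (e >= a) & (e <= b)
    return bool(out) if np.isscalar(energy_kev) else out


def sample_emissions(
    spectrum: EmissionSpectrum, n_decays: int, rng: np.random.Generator
) -> np.ndarray:
    """Photon energies emitted by ``n_decays`` decays.

    Each decay emits each line independently with probability equal to the
    line intensity (per-line Binomial counts), so the expected count of line i
    is ``n_decays * intensity_i``.  The returned array is ordered by line, not
    shuffled; transport treats photons independently so order is irrelevant.
    """
    if n_decays < 0:
        raise ValueError("n_decays must be >= 0")
    if n_decays == 0:
        return np.empty(0)
    counts = [
        rng.binomial(n_decays, l.intensity) if l.intensity < 1.0 else n_decays
        for l in spectrum.lines
    ]
    return np.repeat(spectrum.energies, counts)
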