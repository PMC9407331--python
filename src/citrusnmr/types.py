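"""Core domain containers for the mandarin-extract qNMR pipeline.

The pipeline moves through four representations: an acquisition scheme
(how the spectrometer is run), a free-induction decay (the raw complex
time-domain signal), a frequency-domain spectrum on a ppm axis, and the
sucrose-anchored relative areas of the five marker windows.  All
containers are plain dataclasses; processing steps never mutate their
inputs, they return new objects with an extended ``history``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "Singlet",
    "Doublet",
    "Multiplet",
    "ABSystem",
    "SpinSignal",
    "ExtractComposition",
    "FidRecord",
    "Spectrum",
    "HIGH_FIELD_SCHEME",
    "BENCHTOP_SCHEME",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Spectrometer settings for one experiment.

    Parameters
    ----------
    spectrometer_frequency : float
        1H Larmor frequency in MHz (e.g. 400.13 for a 9.4 T magnet,
        62.32 for a benchtop permanent magnet).
    spectral_width : float
        Sweep width in Hz.
    n_points : int
        Number of complex time-domain points acquired.
    n_scans : int
        Number of averaged transients.
    flip_angle : float
        Excitation pulse angle in degrees.
    relaxation_delay : float
        Inter-scan delay in seconds (bookkeeping only; no T1 bias is
        modelled).
    temperature_label : str
        Free-text temperature annotation, e.g. "298 K" or "room temp".
    """

    spectrometer_frequency: float
    spectral_width: float
    n_points: int
    n_scans: int = 1
    flip_angle: float = 90.0
    relaxation_delay: float = 1.0
    temperature_label: str = ""

    def __post_init__(self) -> None:
        if self.spectrometer_frequency <= 0:
            raise ValueError("spectrometer_frequency must be > 0")
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be > 0")
        if self.n_points < 1024:
            raise ValueError("n_points must be >= 1024")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if not (0.0 < self.flip_angle <= 90.0):
            raise ValueError("flip_angle must be in (0, 90] degrees")

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    @property
    def field_tag(self) -> str:
        """``high_field`` above 100 MHz, ``benchtop`` otherwise."""
        return "high_field" if self.spectrometer_frequency > 100.0 else "benchtop"


#: 9.4 T scheme: 8 kHz sweep, 32 K complex points, 30 deg pulse, 64 scans.
HIGH_FIELD_SCHEME = AcquisitionScheme(
    spectrometer_frequency=400.13,
    spectral_width=8000.0,
    n_points=32768,
    n_scans=64,
    flip_angle=30.0,
    relaxation_delay=1.0,
    temperature_label="298 K",
)

#: Benchtop scheme: 5 kHz sweep, 32 K complex points, 90 deg pulse, 256 scans.
BENCHTOP_SCHEME = AcquisitionScheme(
    spectrometer_frequency=62.32,
    spectral_width=5000.0,
    n_points=32768,
    n_scans=256,
    flip_angle=90.0,
    relaxation_delay=1.0,
    temperature_label="room temperature",
)


@dataclass(frozen=True)
class Singlet:
    pass


@dataclass(frozen=True)
class Doublet:
    j: float  # Hz


@dataclass(frozen=True)
class Multiplet:
    """First-order (weak-coupling) stick multiplet: one splitting per J."""

    js: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "js", tuple(float(j) for j in self.js))


@dataclass(frozen=True)
class ABSystem:
    """Two mutually coupled protons with comparable shift difference and J.

    ``delta_shift`` is the chemical-shift difference between the two
    nuclei in ppm, so the Hz separation (and hence the degree of
    second-order distortion) scales with the spectrometer frequency.
    """

    j: float  # Hz
    delta_shift: float  # ppm


Pattern = Union[Singlet, Doublet, Multiplet, ABSystem]


@dataclass(frozen=True)
class SpinSignal:
    """One resonance (or strongly coupled pair) of a metabolite.

    ``species_fraction`` is the equilibrium fraction of the tautomer or
    anomer carrying the signal; for metabolites whose fractions are
    controlled by :class:`ExtractComposition` (glucose anomers, fructose
    tautomers) the composition value takes precedence at synthesis time.
    ``marker`` distinguishes the five quantification signals from
    optional crowd signals (other ring protons, residual HDO).
    """

    metabolite: str
    center_shift: float  # ppm
    pattern: Pattern
    proton_count: int
    species_fraction: float = 1.0
    marker: bool = True

    def __post_init__(self) -> None:
        if self.proton_count < 1:
            raise ValueError("proton_count must be >= 1")
        if not (0.0 < self.species_fraction <= 1.0):
            raise ValueError("species_fraction must be in (0, 1]")
        if isinstance(self.pattern, (Doublet, ABSystem)) and self.pattern.j < 0:
            raise ValueError("coupling constants must be >= 0")
        if isinstance(self.pattern, Multiplet) and any(j < 0 for j in self.pattern.js):
            raise ValueError("coupling constants must be >= 0")


#: Literature aqueous-equilibrium anomer/tautomer fractions.
ALPHA_GLUCOSE_FRACTION = 0.36
BETA_FURANOSE_FRUCTOSE_FRACTION = 0.25


@dataclass(frozen=True)
class ExtractComposition:
    """Ground-truth analyte amounts for one simulated extract.

    Amounts are in arbitrary concentration units; only ratios matter
    downstream because integrals are anchored to sucrose.
    ``citrate_center_offset`` displaces the citrate methylene AB system
    (in ppm), emulating the temperature/pH dependence of its position.
    ``shift_jitter_scale`` is the standard deviation (ppm) of a global
    random displacement of the whole spectrum per sample, which the
    referencing step must undo.
    """

    sucrose: float
    glucose_total: float
    fructose_total: float
    citric_acid: float
    alpha_glucose_fraction: float = ALPHA_GLUCOSE_FRACTION
    beta_furanose_fructose_fraction: float = BETA_FURANOSE_FRUCTOSE_FRACTION
    shift_jitter_scale: float = 0.002
    citrate_center_offset: float = 0.0
    hdo_amount: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sucrose", "glucose_total", "fructose_total", "citric_acid", "hdo_amount"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("alpha_glucose_fraction", "beta_furanose_fructose_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def beta_glucose_fraction(self) -> float:
        return 1.0 - self.alpha_glucose_fraction

    def scaled(self, factor: float) -> "ExtractComposition":
        """All analyte amounts multiplied by ``factor`` (fractions kept)."""
        return dataclasses.replace(
            self,
            sucrose=self.sucrose * factor,
            glucose_total=self.glucose_total * factor,
            fructose_total=self.fructose_total * factor,
            citric_acid=self.citric_acid * factor,
            hdo_amount=self.hdo_amount * factor,
        )


@dataclass
class FidRecord:
    """Complex time-domain signal plus the scheme that produced it."""

    complex_signal: np.ndarray
    scheme: AcquisitionScheme
    ground_truth: Optional[ExtractComposition] = None
    sample_id: str = ""
    variety_id: str = ""
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.complex_signal = np.asarray(self.complex_signal, dtype=np.complex128)
        if self.complex_signal.shape != (self.scheme.n_points,):
            raise ValueError(
                f"FID length {self.complex_signal.size} != scheme.n_points {self.scheme.n_points}"
            )
        if not np.all(np.isfinite(self.complex_signal)):
            raise ValueError("FID contains non-finite values")


@dataclass
class Spectrum:
    """Frequency-domain spectrum on a descending ppm axis.

    ``history`` is an append-only list of dicts describing every
    processing step applied, with the parameters actually used
    (realised phase angles, alignment shifts, ...).
    """

    ppm_axis: np.ndarray
    real_part: np.ndarray
    imag_part: Optional[np.ndarray]
    scheme: AcquisitionScheme
    history: list = field(default_factory=list)
    sample_id: str = ""
    variety_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.real_part = np.asarray(self.real_part, dtype=float)
        if self.imag_part is not None:
            self.imag_part = np.asarray(self.imag_part, dtype=float)
            if self.imag_part.shape != self.real_part.shape:
                raise ValueError("real and imaginary parts differ in length")
        if self.ppm_axis.shape != self.real_part.shape:
            raise ValueError("ppm axis and intensities differ in length")
        if self.ppm_axis.size >= 2 and not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm axis must be strictly descending")

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    @property
    def digital_resolution(self) -> float:
        """Grid step in ppm (positive)."""
        return float(abs(self.ppm_axis[0] - self.ppm_axis[-1]) / (self.ppm_axis.size - 1))

    def with_history(self, step: str, **params) -> dict:
        """Build a history record (convenience for processing steps)."""
        return {"step": step, **params}

    def copy(self) -> "Spectrum":
        return Spectrum(
            ppm_axis=self.ppm_axis.copy(),
            real_part=self.real_part.copy(),
            imag_part=None if self.imag_part is None else self.imag_part.copy(),
            scheme=self.scheme,
            history=list(self.history),
            sample_id=self.sample_id,
            variety_id=self.variety_id,
            replicate=self.replicate,
        )
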