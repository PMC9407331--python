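"""Fixed-window integration of the five marker signals and
sucrose-anchored relative areas.

The method integrates fixed chemical-shift ranges — no peak fitting or
deconvolution — and scales every area to the sucrose glucosyl anomeric
signal, which is assigned an arbitrary value of 1.00.  Sugar windows are
identical at both fields; the citrate window is field-specific because
the experiment temperature shifts the citrate methylene signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .types import Spectrum

__all__ = [
    "IntegrationWindowSet",
    "RelativeAreas",
    "default_windows",
    "integrate_window",
    "relative_areas",
    "QuantificationError",
]

MARKERS = ("sucrose", "alpha_glucose", "beta_glucose", "fructose", "citrate")


class QuantificationError(RuntimeError):
    """Raised when a sample cannot be quantified (unusable integrals)."""


@dataclass(frozen=True)
class IntegrationWindowSet:
    """Named (ppm_high, ppm_low) integration windows for the five markers."""

    windows: Mapping[str, tuple[float, float]]
    field_tag: str = "custom"

    def __post_init__(self) -> None:
        missing = set(MARKERS) - set(self.windows)
        if missing:
            raise ValueError(f"missing windows: {sorted(missing)}")
        norm = {}
        for name, (a, b) in self.windows.items():
            hi, lo = (a, b) if a >= b else (b, a)
            if hi == lo:
                raise ValueError(f"window {name} has zero width")
            norm[name] = (hi, lo)
        object.__setattr__(self, "windows", norm)
        sugars = [norm[m] for m in MARKERS[:4]]
        for i in range(len(sugars)):
            for k in range(i + 1, len(sugars)):
                hi_i, lo_i = sugars[i]
                hi_k, lo_k = sugars[k]
                if max(lo_i, lo_k) < min(hi_i, hi_k):
                    raise ValueError("sugar windows overlap")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.windows[name]


_SUGAR_WINDOWS = {
    "sucrose": (5.54, 5.32),
    "alpha_glucose": (5.29, 5.16),
    "beta_glucose": (4.63, 4.53),
    "fructose": (4.10, 4.07),
}

_CITRATE_WINDOWS = {"high_field": (3.02, 2.73), "benchtop": (2.81, 2.54)}


def default_windows(field_tag: str) -> IntegrationWindowSet:
    """The method's verbatim integration ranges.

    Sugar windows (both fields): sucrose 5.54-5.32, alpha-glucose
    5.29-5.16, beta-glucose 4.63-4.53, fructose 4.10-4.07 ppm.  Citrate:
    3.02-2.73 ppm at high field, 2.81-2.54 ppm on the benchtop.
    """
    if field_tag not in _CITRATE_WINDOWS:
        raise ValueError(f"unknown field_tag {field_tag!r}; use 'high_field' or 'benchtop'")
    return IntegrationWindowSet(
        windows={**_SUGAR_WINDOWS, "citrate": _CITRATE_WINDOWS[field_tag]},
        field_tag=field_tag,
    )


@dataclass(frozen=True)
class RelativeAreas:
    """Sucrose-anchored marker areas; sucrose is exactly 1.00."""

    sucrose: float
    alpha_glucose: float
    beta_glucose: float
    fructose: float
    citrate: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.sucrose != 1.0:
            raise ValueError("sucrose relative area is 1.00 by definition")
        for name in ("alpha_glucose", "beta_glucose", "fructose", "citrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative relative area for {name}")


def integrate_window(spec: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the real part over a ppm window.

    Bounds may be given in either order.  Result is in intensity x ppm,
    positive for an all-positive absorption signal.
    """
    hi, lo = (window[0], window[1]) if window[0] >= window[1] else (window[1], window[0])
    ppm = spec.ppm_axis
    if hi > ppm[0] or lo < ppm[-1]:
        raise ValueError(
            f"window ({hi}, {lo}) outside spectral range ({ppm[0]:.3f}, {ppm[-1]:.3f})"
        )
    sel = (ppm >= lo) & (ppm <= hi)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 grid points in window ({hi}, {lo})")
    # ascending order for integration
    x = ppm[sel][::-1]
    y = spec.real_part[sel][::-1]
    return float(np.trapezoid(y, x))


def relative_areas(
    spec: Spectrum,
    windows: IntegrationWindowSet,
    proton_normalize: bool = False,
) -> RelativeAreas:
    """Integrate the five windows and anchor them to sucrose = 1.00.

    ``proton_normalize`` additionally divides each area by the number of
    protons in its window (1, 1, 1, 2, 4); the method itself scales raw
    areas only, so this is off by default and not used by the standard
    pipeline.
    """
    raw = {m: integrate_window(spec, windows[m]) for m in MARKERS}
    if raw["sucrose"] <= 0:
        raise QuantificationError(
            f"sucrose anchor integral is {raw['sucrose']:.4g} <= 0; sample unusable"
        )
    for name, area in raw.items():
        if area < 0:
            raise QuantificationError(
                f"negative integral in window '{name}' ({area:.4g}); "
                "check phase/baseline correction"
            )
    if proton_normalize:
        protons = {"sucrose": 1, "alpha_glucose": 1, "beta_glucose": 1,
                   "fructose": 2, "citrate": 4}
        raw = {m: a / protons[m] for m, a in raw.items()}
    anchor = raw["sucrose"]
    return RelativeAreas(
        sucrose=1.0,
        alpha_glucose=raw["alpha_glucose"] / anchor,
        beta_glucose=raw["beta_glucose"] / anchor,
        fructose=raw["fructose"] / anchor,
        citrate=raw["citrate"] / anchor,
        sample_id=spec.sample_id,
    )
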