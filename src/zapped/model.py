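"""Two-pool Z-spectrum forward model.

The Z-spectrum — on-resonance signal as a function of the offset frequency of
a selective saturation pulse — is modeled as the sum of two symmetric spectral
components sharing a common center at zero offset:

    y(x) = F_f * L(x; LW_f) + F_r * L(x; LW_r),      F_f + F_r = 1

where ``y`` is the normalized saturation amount (1 on resonance, tending to 0
at large offset), ``x`` is the offset in Hz, ``F_f``/``F_r`` are the
fractional amplitudes of the free (mobile water) and restricted
(macromolecular) proton pools, and ``LW_f``/``LW_r`` are their full widths at
half maximum in Hz.  The default component shape ``L`` is a Lorentzian,

    L(x; LW) = LW^2 / (LW^2 + 4 x^2),

a Gaussian alternative (same FWHM convention) is provided for model-selection
experiments.  Linewidths map to apparent spin-spin relaxation times via
T2 = 1 / (pi * LW); "apparent" because exchange kinetics, T1 and the
saturation-pulse bandwidth all fold into the fitted width.

Exchange kinetics are deliberately not modeled: the parameterization is
phenomenological, with only three independent variables (F_r, LW_f, LW_r).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Lineshape",
    "PoolParams",
    "ZSpectrum",
    "lorentzian",
    "gaussian",
    "forward_zspectrum",
    "lw_to_t2",
    "t2_to_lw",
]

_FOUR_LN2 = 4.0 * math.log(2.0)


class Lineshape(str, enum.Enum):
    """Spectral component shape, parameterized by FWHM in Hz."""

    LORENTZIAN = "lorentzian"
    GAUSSIAN = "gaussian"

    @classmethod
    def coerce(cls, value: "Lineshape | str") -> "Lineshape":
        if isinstance(value, cls):
            return value
        v = str(value).lower()
        aliases = {"l": "lorentzian", "g": "gaussian"}
        return cls(aliases.get(v, v))


def lw_to_t2(lw: float) -> float:
    """Convert a FWHM linewidth (Hz) to an apparent T2 (seconds).

    T2 = 1 / (pi * LW).
    """
    lw = np.asarray(lw, dtype=float)
    if np.any(lw <= 0):
        raise ValueError("linewidth must be positive")
    return 1.0 / (math.pi * lw)


def t2_to_lw(t2: float) -> float:
    """Convert an apparent T2 (seconds) to a FWHM linewidth (Hz).

    LW = 1 / (pi * T2); mutual inverse of :func:`lw_to_t2`.
    """
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    return 1.0 / (math.pi * t2)


@dataclass(frozen=True)
class PoolParams:
    """Fitted parameter vector for one voxel or ROI.

    Attributes
    ----------
    f_restricted : float
        Fractional amplitude of the restricted (broad) pool, in [0, 1].
    lw_free : float
        FWHM of the free-pool component, Hz.
    lw_restricted : float
        FWHM of the restricted-pool component, Hz.  By labeling convention
        the restricted pool is the broad one, so ``lw_restricted >= lw_free``
        (the two-pool model is exchange-symmetric; without the convention,
        pool identity could swap voxel to voxel).
    """

    f_restricted: float
    lw_free: float
    lw_restricted: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_restricted <= 1.0:
            raise ValueError(f"f_restricted={self.f_restricted} outside [0, 1]")
        if self.lw_free <= 0 or self.lw_restricted <= 0:
            raise ValueError("linewidths must be positive")
        if self.lw_restricted < self.lw_free:
            raise ValueError(
                "lw_restricted must be >= lw_free (the restricted pool is the "
                "broad component by convention); swap the labels"
            )

    @property
    def f_free(self) -> float:
        """Free-pool fraction, 1 - f_restricted."""
        return 1.0 - self.f_restricted

    @property
    def t2_free(self) -> float:
        """Apparent free-pool T2 in seconds."""
        return float(lw_to_t2(self.lw_free))

    @property
    def t2_restricted(self) -> float:
        """Apparent restricted-pool T2 in seconds."""
        return float(lw_to_t2(self.lw_restricted))

    @property
    def t2_free_us(self) -> float:
        """Apparent free-pool T2 in microseconds (reporting unit)."""
        return self.t2_free * 1e6

    @property
    def t2_restricted_us(self) -> float:
        """Apparent restricted-pool T2 in microseconds (reporting unit)."""
        return self.t2_restricted * 1e6

    @classmethod
    def from_t2(
        cls, f_restricted: float, t2_free_us: float, t2_restricted_us: float
    ) -> "PoolParams":
        """Build from T2 values given in microseconds."""
        return cls(
            f_restricted=f_restricted,
            lw_free=float(t2_to_lw(t2_free_us * 1e-6)),
            lw_restricted=float(t2_to_lw(t2_restricted_us * 1e-6)),
        )

    def as_array(self) -> np.ndarray:
        """(f_restricted, lw_free, lw_restricted) as a float array."""
        return np.array([self.f_restricted, self.lw_free, self.lw_restricted])


@dataclass
class ZSpectrum:
    """Paired offsets (Hz) and normalized saturation values for one voxel/ROI.

    ``values[i]`` is the saturation amount at ``offsets[i]``: 1 means the
    signal was fully saturated, 0 means untouched.
    """

    offsets: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.offsets.shape != self.values.shape or self.offsets.ndim != 1:
            raise ValueError("offsets and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.offsets)


def lorentzian(x, amplitude: float, lw: float):
    """Lorentzian component, ``amplitude * lw^2 / (lw^2 + 4 x^2)``.

    Evaluates to ``amplitude`` at x = 0 and ``amplitude / 2`` at
    ``|x| = lw / 2`` (FWHM convention).
    """
    if lw <= 0:
        raise ValueError("linewidth must be positive")
    x = np.asarray(x, dtype=float)
    lw2 = lw * lw
    return amplitude * lw2 / (lw2 + 4.0 * x * x)


def gaussian(x, amplitude: float, lw: float):
    """Gaussian component with FWHM ``lw``: ``amplitude * exp(-4 ln2 x^2 / lw^2)``.

    Same half-maximum convention as :func:`lorentzian`, so a model-selection
    comparison between the two varies the shape, not the width parameterization.
    """
    if lw <= 0:
        raise ValueError("linewidth must be positive")
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-_FOUR_LN2 * (x * x) / (lw * lw))


_SHAPES = {Lineshape.LORENTZIAN: lorentzian, Lineshape.GAUSSIAN: gaussian}


def _evaluate(
    f_restricted: float,
    lw_free: float,
    lw_restricted: float,
    offsets: np.ndarray,
    shape_free,
    shape_restricted,
) -> np.ndarray:
    # Internal unchecked evaluation shared with the fitting residual.
    return shape_free(offsets, 1.0 - f_restricted, lw_free) + shape_restricted(
        offsets, f_restricted, lw_restricted
    )


def forward_zspectrum(
    params: PoolParams,
    offsets,
    lineshape_free: Lineshape | str = Lineshape.LORENTZIAN,
    lineshape_restricted: Lineshape | str = Lineshape.LORENTZIAN,
) -> ZSpectrum:
    """Evaluate the two-pool model over an offset schedule.

    Parameters
    ----------
    params : PoolParams
        Pool fractions and linewidths.
    offsets : array-like or OffsetSchedule
        Offset frequencies in Hz.
    lineshape_free, lineshape_restricted : Lineshape
        Component shapes; both Lorentzian by default (the combination that
        fits broad-band MT spectra of brain tissue best).

    Returns
    -------
    ZSpectrum
        With ``values[i] = f_free * shape_f(x_i) + f_restricted * shape_r(x_i)``,
        equal to 1 at x = 0.
    """
    x = np.asarray(getattr(offsets, "offsets", offsets), dtype=float)
    if x.size == 0:
        raise ValueError("offset schedule is empty")
    sf = _SHAPES[Lineshape.coerce(lineshape_free)]
    sr = _SHAPES[Lineshape.coerce(lineshape_restricted)]
    y = _evaluate(params.f_restricted, params.lw_free, params.lw_restricted, x, sf, sr)
    return ZSpectrum(offsets=x, values=y)
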