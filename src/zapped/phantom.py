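"""Synthetic Z-spectrum phantoms and cohorts with known ground truth.

Real broad-band MT acquisitions of brain are emulated by digital phantoms:
a 2-D label image assigns each voxel a tissue class (GM, WM, CSF, tumor...),
each class carries two-pool parameters drawn from published healthy- and
tumor-tissue values, and the signal stack is generated voxel-wise as

    S(x) = s0 * (1 - y_model(x)) + noise,   noise ~ Normal(0, sigma * s0)

on a chosen offset schedule.  CSF carries no MT-active restricted pool and
contributes only direct saturation, modeled as a single narrow Lorentzian
whose width matches the ~400 Hz saturation-pulse bandwidth.

Multi-subject cohorts emulate an aging study: white-matter F_r declines
linearly with age (reflecting myelin loss) while gray-matter parameters are
age-independent; per-subject scatter about the line and acquisition noise
are both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import PoolParams, forward_zspectrum, lorentzian
from .sampling import OffsetSchedule, default_schedule

__all__ = [
    "TissueSpec",
    "CohortSpec",
    "Subject",
    "tissue_presets",
    "make_layout",
    "make_phantom",
    "make_cohort",
    "TABLE1_AGES",
]

# Ages and sex pattern of the healthy reference cohort (9 adults, 7M/2F).
TABLE1_AGES: tuple[int, ...] = (33, 35, 36, 38, 48, 51, 55, 59, 71)
_SEX_PATTERN: tuple[str, ...] = ("M", "M", "F", "F", "M", "M", "M", "M", "M")

# Direct-saturation width for MT-inactive tissue, Hz (saturation bandwidth).
CSF_DIRECT_SAT_LW = 400.0

# Age regression of white-matter F_r in healthy adults.
WM_AGE_INTERCEPT = 0.355
WM_AGE_SLOPE = -0.00165
# Per-subject scatter about the age line, chosen so a 9-subject cohort with
# the reference ages reproduces the observed R^2 ~ 0.66 regime.
WM_SUBJECT_SD = 0.0155


@dataclass(frozen=True)
class TissueSpec:
    """One tissue class of a phantom.

    ``params=None`` marks an MT-inactive tissue (CSF): its spectrum is flat
    except for direct saturation near resonance, modeled as a narrow
    Lorentzian of width ``direct_sat_lw``.
    """

    name: str
    params: PoolParams | None
    s0: float = 1000.0
    direct_sat_lw: float = CSF_DIRECT_SAT_LW


def tissue_presets() -> dict[str, TissueSpec]:
    """Named tissue presets from published healthy and tumor values.

    Fractions and apparent T2s (in microseconds) are converted to the
    internal (F_r, LW_f, LW_r) parameterization; every preset satisfies
    LW_r > LW_f (restricted pool broad).
    """
    table = {
        # name: (F_r, T2_f us, T2_r us)
        "GM-healthy": (0.17, 785.0, 17.7),
        "WM-healthy": (0.28, 672.0, 23.4),
        "WM-lymphoma": (0.16, 873.0, 30.6),
        "GM-edema-lymphoma": (0.10, 928.0, 19.0),
        "WM-glioma": (0.09, 948.0, 18.1),
        # deep gray/white structures, basal-ganglia level
        "Caudate": (0.20, 599.0, 14.5),
        "Pallidus": (0.28, 537.0, 20.9),
        "Thalamus": (0.26, 550.0, 19.2),
        "Hippocampus": (0.21, 599.0, 16.3),
        "WM-deep": (0.30, 641.0, 22.1),
    }
    presets = {
        name: TissueSpec(name=name, params=PoolParams.from_t2(fr, t2f, t2r))
        for name, (fr, t2f, t2r) in table.items()
    }
    presets["CSF"] = TissueSpec(name="CSF", params=None)
    return presets


def make_layout(
    geometry: str = "two-disc", matrix: int = 64, tumor: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Built-in 2-D label geometries.

    ``two-disc``
        GM annulus around a WM disc (labels: GM=1, WM=2).
    ``cohort-slice``
        GM ribbon + WM core + two CSF "ventricles", optionally a tumor
        insert in WM (labels: GM=1, WM=2, CSF=3[, tumor=4]).

    Returns (label image, label names in label order starting at 1).
    """
    yy, xx = np.mgrid[0:matrix, 0:matrix]
    c = (matrix - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    labels = np.zeros((matrix, matrix), dtype=np.int16)
    if geometry == "two-disc":
        names = ["GM", "WM"]
        labels[r <= 0.45 * matrix] = 1  # GM annulus background
        labels[r <= 0.28 * matrix] = 2  # WM core
    elif geometry == "cohort-slice":
        names = ["GM", "WM", "CSF"]
        labels[r <= 0.45 * matrix] = 1
        labels[r <= 0.32 * matrix] = 2
        for dx in (-0.12, 0.12):  # paired ventricles
            rv = np.hypot(yy - c, xx - (c + dx * matrix))
            labels[rv <= 0.07 * matrix] = 3
        if tumor:
            names.append("tumor")
            rt = np.hypot(yy - (c - 0.18 * matrix), xx - c)
            labels[(rt <= 0.08 * matrix) & (labels == 2)] = 4
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return labels, names


def _tissue_spectrum(tissue: TissueSpec, schedule: OffsetSchedule) -> np.ndarray:
    if tissue.params is None:
        return np.asarray(
            lorentzian(schedule.offsets, 1.0, tissue.direct_sat_lw), dtype=float
        )
    return forward_zspectrum(tissue.params, schedule).values


def make_phantom(
    layout: np.ndarray | str,
    tissues: Sequence[TissueSpec],
    schedule: OffsetSchedule | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    s0_background: float = 0.0,
    matrix: int = 64,
):
    """Generate a synthetic signal stack with ground truth.

    Parameters
    ----------
    layout : label image or geometry name
        Integer label image (0 = background; label i = ``tissues[i-1]``),
        or a built-in geometry name accepted by :func:`make_layout`.
    tissues : sequence of TissueSpec
        One spec per label value, in label order.
    noise_sigma : float
        Gaussian noise SD as a fraction of each tissue's baseline signal.
        Gaussian (not Rician) keeps the least-squares model correctly
        specified; at ROI-average SNR the difference is negligible.
    seed : int
        Seeds the noise generator; identical calls are bit-identical.

    Returns
    -------
    stack : ndarray (ny, nx, n_offsets)
    labels : ndarray (ny, nx) int
    truth : dict
        Ground-truth maps (``f_restricted``, ``f_free``, ``t2_free_us``,
        ``t2_restricted_us`` — NaN for background and MT-inactive tissue),
        the noise-free baseline ``s0`` volume, and the tissue table.
    """
    schedule = schedule or default_schedule()
    if isinstance(layout, str):
        labels, names = make_layout(layout, matrix=matrix)
        by_name = {t.name: t for t in tissues}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ValueError(f"layout labels missing from tissue list: {missing}")
        tissues = [by_name[n] for n in names]
    else:
        labels = np.asarray(layout, dtype=np.int16)
        if labels.max() > len(tissues):
            raise ValueError(
                f"layout contains label {labels.max()} but only "
                f"{len(tissues)} tissues were given"
            )

    shape = labels.shape
    nfreq = len(schedule)
    stack = np.zeros(shape + (nfreq,), dtype=float)
    s0 = np.full(shape, s0_background, dtype=float)
    truth = {
        k: np.full(shape, np.nan)
        for k in ("f_restricted", "f_free", "t2_free_us", "t2_restricted_us")
    }
    for i, tissue in enumerate(tissues, start=1):
        sel = labels == i
        if not np.any(sel):
            continue
        y = _tissue_spectrum(tissue, schedule)
        stack[sel] = tissue.s0 * (1.0 - y)
        s0[sel] = tissue.s0
        if tissue.params is not None:
            p = tissue.params
            truth["f_restricted"][sel] = p.f_restricted
            truth["f_free"][sel] = p.f_free
            truth["t2_free_us"][sel] = p.t2_free_us
            truth["t2_restricted_us"][sel] = p.t2_restricted_us
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sigma, stack.shape) * s0[..., None]
    truth["s0"] = s0
    truth["tissues"] = {i + 1: t for i, t in enumerate(tissues)}
    return stack, labels, truth


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic aging cohort.

    Defaults reproduce the healthy-adult study conditions: nine subjects
    aged 33-71 (7M/2F), WM F_r on the line ``intercept + slope * age`` with
    per-subject scatter ``subject_sd``, GM parameters age-independent.
    """

    n_subjects: int = 9
    ages: tuple[int, ...] | None = None
    age_range: tuple[int, int] = (33, 71)
    wm_age_slope: float = WM_AGE_SLOPE
    wm_age_intercept: float = WM_AGE_INTERCEPT
    subject_sd: float = WM_SUBJECT_SD
    gm_params: PoolParams = field(
        default_factory=lambda: PoolParams.from_t2(0.17, 785.0, 17.7)
    )
    wm_t2_free_us: float = 672.0
    wm_t2_restricted_us: float = 23.4
    noise_sigma: float = 0.005
    seed: int = 20150313
    geometry: str = "cohort-slice"
    matrix: int = 64


@dataclass
class Subject:
    """One synthetic cohort member with its acquisition and ground truth."""

    subject_id: str
    age: float
    sex: str
    stack: np.ndarray
    labels: np.ndarray
    truth: dict
    wm_f_restricted_true: float


def _cohort_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.ages is not None:
        if len(spec.ages) != spec.n_subjects:
            raise ValueError("ages length must equal n_subjects")
        return np.asarray(spec.ages, dtype=float)
    if spec.n_subjects % len(TABLE1_AGES) == 0:
        return np.tile(TABLE1_AGES, spec.n_subjects // len(TABLE1_AGES)).astype(float)
    lo, hi = spec.age_range
    return rng.uniform(lo, hi, spec.n_subjects)


def make_cohort(
    spec: CohortSpec, schedule: OffsetSchedule | None = None
) -> list[Subject]:
    """Generate a multi-subject cohort of phantoms.

    Each subject's WM restricted fraction is drawn from the age line plus
    Normal(0, subject_sd) scatter; draws falling outside (0, 0.6) are
    resampled.  GM parameters are shared across ages.  The per-subject noise
    realizations derive independently from ``spec.seed``.
    """
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(spec.seed)
    ages = _cohort_ages(spec, rng)
    presets = tissue_presets()
    subjects = []
    for i, age in enumerate(ages):
        for _ in range(1000):
            fr = spec.wm_age_intercept + spec.wm_age_slope * age
            fr += rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
            if 0.0 < fr < 0.6:
                break
        else:
            raise RuntimeError("could not draw WM F_r inside (0, 0.6)")
        wm = TissueSpec(
            name="WM",
            params=PoolParams.from_t2(fr, spec.wm_t2_free_us, spec.wm_t2_restricted_us),
        )
        gm = TissueSpec(name="GM", params=spec.gm_params)
        tissues = [gm, wm, presets["CSF"]]
        labels, names = make_layout(spec.geometry, matrix=spec.matrix)
        stack, labels, truth = make_phantom(
            labels,
            tissues,
            schedule,
            noise_sigma=spec.noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            Subject(
                subject_id=f"sub-{i + 1:03d}",
                age=float(age),
                sex=_SEX_PATTERN[i % len(_SEX_PATTERN)],
                stack=stack,
                labels=labels,
                truth=truth,
                wm_f_restricted_true=float(fr),
            )
        )
    return subjects
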