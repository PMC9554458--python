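"""PK/PD indices, probability of target attainment and regimen classification.

Aminoglycoside efficacy is concentration-driven: the indices evaluated
are the peak-to-MIC ratio Cmax/MIC and the percentage of the dosing
interval spent above the MIC (T>MIC).  Toxicity surrogates are the
trough Cmin (accumulation) and the absolute peak Cmax.  For a simulated
cohort, the probability of target attainment (PTA) of a criterion at a
given MIC is the percentage of subjects meeting it; a regimen is called
effective when PTA >= 90% for the efficacy criteria and safe when
PTA <= 10% for the toxicity criteria.

Indices are evaluated over the first dosing interval by default (drug
accumulation is negligible at q24-48 h dosing given the neonatal
half-life of ~5-7 h); any later interval can be selected via ``start``.
Cmax is the profile maximum over the evaluation window, which for this
model occurs at the end of the infusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ConcentrationProfile

__all__ = [
    "DEFAULT_MIC_GRID",
    "PKPDIndices",
    "PKPDCriteria",
    "PTAResult",
    "compute_indices",
    "time_above_threshold",
    "pta",
    "mic_breakpoint",
    "classify_regimen",
    "RegimenVerdict",
]

logger = logging.getLogger(__name__)

#: MIC grid used for PTA-vs-MIC curves: 0.05 to 2.0 mg/L in 0.05 steps
#: (no MIC above the 2 mg/L clinical breakpoint is considered).
DEFAULT_MIC_GRID = np.round(np.arange(0.05, 2.0 + 1e-9, 0.05), 10)

EFFICACY_CRITERIA = ("cmax_mic", "t_above_mic")
TOXICITY_CRITERIA = ("cmin_toxicity", "cmax_toxicity")


@dataclass(frozen=True)
class PKPDCriteria:
    """Target thresholds and PTA decision levels.

    All criterion comparisons are inclusive (>=); the PTA decision
    thresholds are inclusive as well (effective when PTA >= 90%, safe
    when PTA <= 10%).
    """

    cmax_mic_ratio: float = 8.0
    t_above_mic_percent: float = 60.0
    cmin_toxic: float = 2.0  # mg/L
    cmax_toxic: float = 25.0  # mg/L
    pta_effective: float = 90.0  # %
    pta_safe: float = 10.0  # %

    def __post_init__(self) -> None:
        for name in ("cmax_mic_ratio", "t_above_mic_percent", "cmin_toxic", "cmax_toxic",
                     "pta_effective", "pta_safe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PKPDIndices:
    """Exposure indices of one subject over one evaluation interval."""

    cmax: float  # mg/L, maximum blood concentration over the interval
    cmin: float  # mg/L, concentration at the interval end
    t_above_mic: float  # % of the interval with Cb > MIC
    interval: float  # h
    mic: float  # mg/L

    def __post_init__(self) -> None:
        if not self.cmax >= self.cmin >= 0:
            raise ValueError(f"expected cmax >= cmin >= 0, got cmax={self.cmax}, cmin={self.cmin}")
        if not 0 <= self.t_above_mic <= 100:
            raise ValueError(f"t_above_mic must be in [0, 100], got {self.t_above_mic}")


def time_above_threshold(times: np.ndarray, conc: np.ndarray, threshold: float) -> float:
    """Total time with conc > threshold, linear interpolation at crossings."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    above = c > threshold
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    a0, a1 = above[:-1], above[1:]
    total = np.sum(dt[a0 & a1])
    crossing = a0 != a1
    if np.any(crossing):
        # fraction of the step spent on the upper side of the threshold
        frac = np.abs(np.where(a0, c0, c1)[crossing] - threshold) / np.abs(c0 - c1)[crossing]
        total += np.sum(dt[crossing] * frac)
    return float(total)


def compute_indices(
    profile: ConcentrationProfile,
    mic: float,
    interval: float | None = None,
    start: float = 0.0,
) -> PKPDIndices:
    """Evaluate Cmax, Cmin and T>MIC over one dosing interval.

    The profile grid must cover [start, start+interval] and contain the
    end-of-infusion time (guaranteed by ``simulate_profile``).  A
    non-positive MIC is degenerate: T>MIC is defined as 100% and the
    event is logged.
    """
    if interval is None:
        interval = profile.regimen.interval
    end = start + interval
    if profile.times[-1] < end - 1e-9:
        raise ValueError(
            f"profile covers [0, {profile.times[-1]}] but the evaluation "
            f"interval ends at {end}"
        )
    mask = (profile.times >= start - 1e-10) & (profile.times <= end + 1e-10)
    t = profile.times[mask]
    c = profile.Cb[mask]
    cmax = float(np.max(c))
    cmin = float(profile.conc_at(end))
    if mic <= 0:
        logger.warning("non-positive MIC %s: T>MIC defined as 100%%", mic)
        t_above = 100.0
    else:
        t_above = 100.0 * time_above_threshold(t, c, mic) / interval
    return PKPDIndices(
        cmax=cmax, cmin=cmin, t_above_mic=min(t_above, 100.0), interval=interval, mic=mic
    )


@dataclass(frozen=True)
class PTAResult:
    """PTA (%) per criterion over a MIC grid for one cohort x regimen.

    MIC-dependent criteria vary along ``mic_grid``; the trough/peak
    toxicity criteria are MIC-independent and stored once.
    """

    mic_grid: np.ndarray
    cmax_mic: np.ndarray  # % per MIC
    t_above_mic: np.ndarray | None  # % per MIC, None when only Cmax data given
    cmin_toxicity: float | None  # %
    cmax_toxicity: float | None  # %
    n: int
    criteria: PKPDCriteria = field(default_factory=PKPDCriteria, repr=False)
    label: str = ""

    def at_mic(self, mic: float) -> dict[str, float | None]:
        """All four PTA values at one grid MIC."""
        idx = int(np.argmin(np.abs(self.mic_grid - mic)))
        if abs(self.mic_grid[idx] - mic) > 1e-9:
            raise ValueError(f"MIC {mic} is not on the evaluated grid")
        return {
            "cmax_mic": float(self.cmax_mic[idx]),
            "t_above_mic": None if self.t_above_mic is None else float(self.t_above_mic[idx]),
            "cmin_toxicity": self.cmin_toxicity,
            "cmax_toxicity": self.cmax_toxicity,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy PTA curves: MIC, criterion, PTA_percent."""
        frames = [
            pd.DataFrame({"MIC": self.mic_grid, "criterion": "cmax_mic", "PTA_percent": self.cmax_mic})
        ]
        if self.t_above_mic is not None:
            frames.append(
                pd.DataFrame(
                    {"MIC": self.mic_grid, "criterion": "t_above_mic", "PTA_percent": self.t_above_mic}
                )
            )
        for name, value in (("cmin_toxicity", self.cmin_toxicity), ("cmax_toxicity", self.cmax_toxicity)):
            if value is not None:
                frames.append(pd.DataFrame({"MIC": [np.nan], "criterion": [name], "PTA_percent": [value]}))
        return pd.concat(frames, ignore_index=True)


def pta(
    profiles: Sequence[ConcentrationProfile] | None = None,
    *,
    cmax: Sequence[float] | None = None,
    criteria: PKPDCriteria | None = None,
    mic_grid: Sequence[float] | None = None,
    interval: float | None = None,
    start: float = 0.0,
    label: str = "",
) -> PTAResult:
    """Probability of target attainment across a cohort and a MIC grid.

    Either full concentration ``profiles`` (all four criteria) or a bare
    array of per-subject ``cmax`` values (ratio and peak-toxicity
    criteria only, used for analytic cross-checks) must be supplied.
    PTA = 100 x (subjects meeting the criterion) / n, per criterion and
    MIC.  Deterministic given the cohort and invariant to subject order.
    """
    criteria = criteria or PKPDCriteria()
    grid = np.asarray(DEFAULT_MIC_GRID if mic_grid is None else mic_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("mic_grid must be a non-empty strictly increasing 1-D array")
    if (profiles is None) == (cmax is None):
        raise ValueError("supply exactly one of profiles or cmax")

    if profiles is not None:
        if len(profiles) == 0:
            raise ValueError("empty cohort")
        n = len(profiles)
        cmax_v = np.empty(n)
        cmin_v = np.empty(n)
        windows = []
        for i, prof in enumerate(profiles):
            idx = compute_indices(prof, mic=grid[0], interval=interval, start=start)
            cmax_v[i] = idx.cmax
            cmin_v[i] = idx.cmin
            end = start + idx.interval
            mask = (prof.times >= start - 1e-10) & (prof.times <= end + 1e-10)
            windows.append((prof.times[mask], prof.Cb[mask], idx.interval))
        t_above_pta = np.empty(grid.size)
        for j, mic in enumerate(grid):
            frac = [
                100.0 * time_above_threshold(t, c, mic) / width >= criteria.t_above_mic_percent
                for t, c, width in windows
            ]
            t_above_pta[j] = 100.0 * np.mean(frac)
        cmin_tox = 100.0 * float(np.mean(cmin_v >= criteria.cmin_toxic))
        cmax_tox = 100.0 * float(np.mean(cmax_v >= criteria.cmax_toxic))
    else:
        cmax_v = np.asarray(cmax, dtype=float)
        if cmax_v.size == 0:
            raise ValueError("empty cohort")
        n = cmax_v.size
        t_above_pta = None
        cmin_tox = None
        cmax_tox = 100.0 * float(np.mean(cmax_v >= criteria.cmax_toxic))

    ratio_pta = np.array(
        [100.0 * np.mean(cmax_v / mic >= criteria.cmax_mic_ratio) for mic in grid]
    )
    return PTAResult(
        mic_grid=grid,
        cmax_mic=ratio_pta,
        t_above_mic=t_above_pta,
        cmin_toxicity=cmin_tox,
        cmax_toxicity=cmax_tox,
        n=n,
        criteria=criteria,
        label=label,
    )


def mic_breakpoint(
    result: PTAResult,
    criterion: str = "cmax_mic",
    threshold: float = 90.0,
) -> float | None:
    """Largest grid MIC still attaining PTA >= threshold.

    Returns ``None`` when no grid MIC reaches the threshold.  The PTA of
    both efficacy criteria is mathematically non-increasing in MIC on a
    fixed cohort; if the curve is non-monotone beyond that guarantee a
    warning is emitted and the last down-crossing is used.
    """
    if criterion not in EFFICACY_CRITERIA:
        raise ValueError(f"criterion must be one of {EFFICACY_CRITERIA}")
    curve = result.cmax_mic if criterion == "cmax_mic" else result.t_above_mic
    if curve is None:
        raise ValueError(f"{criterion} PTA was not evaluated for this result")
    meets = curve >= threshold
    if not np.any(meets):
        return None
    if np.any(np.diff(curve) > 1e-9):
        warnings.warn(
            "PTA curve is not non-increasing in MIC; using the last down-crossing",
            RuntimeWarning,
            stacklevel=2,
        )
    last = int(np.max(np.nonzero(meets)))
    return float(result.mic_grid[last])


@dataclass(frozen=True)
class RegimenVerdict:
    """Efficacy/safety classification of one regimen at one MIC."""

    per_criterion: dict[str, bool]
    effective: bool  # both efficacy criteria attain PTA >= 90%
    safe: bool  # both toxicity criteria stay at PTA <= 10%
    mic: float
    pta_values: dict[str, float | None]


def classify_regimen(
    result: PTAResult,
    mic: float = 1.0,
    criteria: PKPDCriteria | None = None,
) -> RegimenVerdict:
    """Classify a regimen as effective and/or safe at a reference MIC."""
    criteria = criteria or result.criteria
    values = result.at_mic(mic)
    per: dict[str, bool] = {}
    for name in EFFICACY_CRITERIA:
        if values[name] is not None:
            per[name] = values[name] >= criteria.pta_effective
    for name in TOXICITY_CRITERIA:
        if values[name] is not None:
            per[name] = values[name] <= criteria.pta_safe
    effective = all(per.get(name, False) for name in EFFICACY_CRITERIA)
    safe = all(per.get(name, False) for name in TOXICITY_CRITERIA)
    return RegimenVerdict(per_criterion=per, effective=effective, safe=safe, mic=mic, pta_values=values)
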