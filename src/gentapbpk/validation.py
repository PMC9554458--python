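"""Predictive-performance metrics and the simulation-based predictive check.

Bias and precision of model predictions against observations are
summarised with the prediction error PE(%) = (PRED - OBS)/OBS x 100,
its mean (MPE), the average fold error AFE = 10^mean(log10 PRED/OBS)
(geometric bias) and the absolute average fold error
AAFE = 10^mean(|log10 PRED/OBS|) (geometric precision); predictions are
conventionally called satisfactory when AFE and AAFE fall within the
0.5-to-2-fold band.

The visual-predictive-check machinery simulates a large virtual cohort,
extracts empirical percentiles of the simulated concentrations at the
nominal sampling times, and reports the fraction of dose-normalized
observations falling inside the 90% prediction interval (5th-95th
simulated percentiles).  Model adequacy is flagged when observations are
distributed within that band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ConcentrationProfile

__all__ = [
    "PredObsSet",
    "ValidationReport",
    "VPCResult",
    "prediction_error",
    "fold_error_metrics",
    "dose_normalize",
    "vpc",
]

PRED_OBS_COLUMNS = ("subject_id", "endpoint", "pred", "obs")


@dataclass(frozen=True)
class PredObsSet:
    """Matched prediction/observation pairs, one row per pair.

    Required columns: subject_id, endpoint, pred, obs.  Optional columns
    dose_per_kg and standard_dose_per_kg enable dose normalization.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PRED_OBS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"PredObsSet is missing columns {missing}")
        if len(self.data) == 0:
            raise ValueError("PredObsSet must contain at least one pair")

    def endpoints(self) -> list[str]:
        return list(dict.fromkeys(self.data["endpoint"]))


def prediction_error(pred: float, obs: float) -> float:
    """Prediction error in percent: (PRED - OBS) / OBS x 100."""
    if obs == 0:
        raise ValueError("prediction error is undefined for OBS = 0")
    return (pred - obs) / obs * 100.0


@dataclass(frozen=True)
class ValidationReport:
    """Per-endpoint MPE/AFE/AAFE summary with the 0.5-2-fold flag."""

    table: pd.DataFrame  # endpoint, n, MPE_percent, AFE, AAFE, within_2fold

    def for_endpoint(self, endpoint: str) -> pd.Series:
        rows = self.table[self.table["endpoint"] == endpoint]
        if rows.empty:
            raise KeyError(endpoint)
        return rows.iloc[0]

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def fold_error_metrics(pairs: PredObsSet) -> ValidationReport:
    """MPE, AFE and AAFE per endpoint.

    MPE is the arithmetic mean of the per-pair PE(%); AFE and AAFE are
    computed on log10 fold ratios and require strictly positive PRED and
    OBS (PE alone tolerates any non-zero OBS).
    """
    records = []
    for endpoint, grp in pairs.data.groupby("endpoint", sort=False):
        pred = grp["pred"].to_numpy(dtype=float)
        obs = grp["obs"].to_numpy(dtype=float)
        if np.any(obs == 0):
            raise ValueError(f"endpoint {endpoint!r} has OBS = 0 pairs")
        if np.any(pred <= 0) or np.any(obs <= 0):
            raise ValueError(
                f"endpoint {endpoint!r} has non-positive values; AFE/AAFE are undefined"
            )
        log_ratio = np.log10(pred / obs)
        mpe = float(np.mean((pred - obs) / obs * 100.0))
        afe = float(10.0 ** np.mean(log_ratio))
        aafe = float(10.0 ** np.mean(np.abs(log_ratio)))
        records.append(
            {
                "endpoint": endpoint,
                "n": len(grp),
                "MPE_percent": mpe,
                "AFE": afe,
                "AAFE": aafe,
                "within_2fold": bool(0.5 <= afe <= 2.0 and aafe <= 2.0),
            }
        )
    return ValidationReport(table=pd.DataFrame.from_records(records))


def dose_normalize(conc: float, dose_per_kg: float, standard_dose_per_kg: float) -> float:
    """Rescale an observed concentration to the standard dose.

    Valid under model linearity: conc x standard/actual dose per kg.
    """
    if not dose_per_kg > 0:
        raise ValueError(f"actual dose per kg must be positive, got {dose_per_kg}")
    if not standard_dose_per_kg > 0:
        raise ValueError(f"standard dose per kg must be positive, got {standard_dose_per_kg}")
    return conc * standard_dose_per_kg / dose_per_kg


@dataclass(frozen=True)
class VPCResult:
    """Percentile bands, prediction intervals and observed coverage."""

    bands: pd.DataFrame  # time_h, percentile, value
    intervals: pd.DataFrame  # time_h, pi (50/90), lower, upper
    coverage: float  # fraction of observations inside the 90% PI
    coverage_by_time: pd.DataFrame  # time_h, n_obs, inside_90pi_fraction
    n_simulated: int
    adequate: bool = field(default=False)

    def band(self, time_h: float, percentile: float) -> float:
        rows = self.bands[
            (np.isclose(self.bands["time_h"], time_h))
            & (np.isclose(self.bands["percentile"], percentile))
        ]
        if rows.empty:
            raise KeyError((time_h, percentile))
        return float(rows["value"].iloc[0])


def vpc(
    observed: pd.DataFrame,
    profiles: Sequence[ConcentrationProfile],
    times: Sequence[float] = (2.0, 24.0),
    percentiles: Sequence[float] = (10.0, 25.0, 50.0, 75.0, 90.0),
    standard_dose_per_kg: float | None = None,
    min_cohort: int = 100,
) -> VPCResult:
    """Predictive check of simulated percentile bands against observations.

    Parameters
    ----------
    observed : frame with columns time_h, conc_mg_L and (when
        ``standard_dose_per_kg`` is given) dose_per_kg; observations are
        binned to the nearest nominal time.
    profiles : simulated cohort (>= ``min_cohort`` subjects).
    times : nominal sampling times of the design.

    Empirical percentiles use linear interpolation between order
    statistics.  The 90% prediction interval is the 5th-95th percentile
    band, the 50% interval the 25th-75th.
    """
    if len(profiles) < min_cohort:
        raise ValueError(f"need >= {min_cohort} simulated subjects, got {len(profiles)}")
    if len(observed) == 0:
        raise ValueError("no observations supplied")
    for col in ("time_h", "conc_mg_L"):
        if col not in observed.columns:
            raise ValueError(f"observed frame is missing column {col!r}")

    times = np.asarray(times, dtype=float)
    sims = np.stack([p.conc_at(times) for p in profiles])  # (n_subjects, n_times)

    band_rows = []
    for j, t in enumerate(times):
        for q in percentiles:
            band_rows.append(
                {"time_h": t, "percentile": q, "value": float(np.percentile(sims[:, j], q))}
            )
    bands = pd.DataFrame(band_rows)

    pi_rows = []
    for j, t in enumerate(times):
        for pi, (lo, hi) in (("50", (25, 75)), ("90", (5, 95))):
            pi_rows.append(
                {
                    "time_h": t,
                    "pi": pi,
                    "lower": float(np.percentile(sims[:, j], lo)),
                    "upper": float(np.percentile(sims[:, j], hi)),
                }
            )
    intervals = pd.DataFrame(pi_rows)

    conc = observed["conc_mg_L"].to_numpy(dtype=float)
    if standard_dose_per_kg is not None:
        if "dose_per_kg" not in observed.columns:
            raise ValueError("dose normalization requested but dose_per_kg column is absent")
        doses = observed["dose_per_kg"].to_numpy(dtype=float)
        conc = np.array(
            [dose_normalize(c, d, standard_dose_per_kg) for c, d in zip(conc, doses)]
        )
    obs_times = observed["time_h"].to_numpy(dtype=float)
    nearest = times[np.argmin(np.abs(obs_times[:, None] - times[None, :]), axis=1)]

    inside = np.zeros(len(conc), dtype=bool)
    cov_rows = []
    for t in times:
        sel = nearest == t
        row = intervals[(intervals["time_h"] == t) & (intervals["pi"] == "90")].iloc[0]
        inside[sel] = (conc[sel] >= row["lower"]) & (conc[sel] <= row["upper"])
        cov_rows.append(
            {
                "time_h": t,
                "n_obs": int(np.sum(sel)),
                "inside_90pi_fraction": float(np.mean(inside[sel])) if np.any(sel) else np.nan,
            }
        )
    coverage = float(np.mean(inside))
    return VPCResult(
        bands=bands,
        intervals=intervals,
        coverage=coverage,
        coverage_by_time=pd.DataFrame(cov_rows),
        n_simulated=len(profiles),
        adequate=bool(coverage >= 0.80),
    )
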