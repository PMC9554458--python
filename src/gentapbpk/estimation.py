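"""Population parameter estimation from TDM data by iterative two-stage (ITS).

The estimable parameter is the glomerular filtration rate (GFR), the
covariate the model is most sensitive to.  Between-subject variability
is log-normal: GFR_i = typical * exp(eta_i) with eta_i ~ N(0, omega^2).
The residual model is proportional: DV_ij = f_ij * (1 + eps),
eps ~ N(0, sigma^2) - the standard choice for immunoassay TDM, whose
precision scales with the measured level.

One ITS iteration alternates

(a) a maximum-a-posteriori (MAP) fit of eta_i per subject against the
    PBPK model predictions at that subject's sampling times, returning
    the posterior mode and a curvature-based variance, and
(b) a population update on the log scale: the typical value moves by the
    mean of the eta modes, and omega^2 is re-estimated as
    mean(eta_i^2 + var_i) - the curvature term corrects the shrinkage
    bias of plugging in modes alone.  sigma^2 is re-estimated from the
    pooled proportional residuals.

Iteration stops when the relative change of every population parameter
falls below ``tol``.  The procedure is deterministic given the dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import DosingRegimen, PBPKParameters, predict_conc

__all__ = [
    "TDM_COLUMNS",
    "TDMDataset",
    "SubjectRecord",
    "PopulationModel",
    "IndividualEstimate",
    "EstimateResult",
    "map_individual",
    "its_fit",
]

#: NONMEM-flavoured TDM table columns (GA/PNA/BLQ are dataset extras).
TDM_COLUMNS = ("ID", "TIME", "DV", "AMT", "RATE", "WT", "GROUP")

#: Lower limit of quantification of the reference assay, mg/L.
LLOQ_DEFAULT = 0.3


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's dosing and sampled concentrations."""

    subject_id: str
    group: str
    tbw: float  # kg
    dose_per_kg: float  # mg/kg
    infusion_duration: float  # h
    times: np.ndarray  # h, quantifiable samples only
    conc: np.ndarray  # mg/L
    n_blq: int = 0

    def regimen(self, interval: float | None = None) -> DosingRegimen:
        """Single-dose regimen covering this subject's sampling span."""
        if interval is None:
            last = float(self.times.max()) if self.times.size else 24.0
            interval = max(last + 1.0, self.infusion_duration * 2, 24.0)
        return DosingRegimen(
            dose_per_kg=self.dose_per_kg,
            interval=interval,
            infusion_duration=self.infusion_duration,
            n_doses=1,
        )


@dataclass(frozen=True)
class TDMDataset:
    """TDM table (one dose row + observation rows per subject).

    Columns: ID, TIME, DV, AMT, RATE, WT, GROUP and optionally GA, PNA,
    BLQ.  Dose rows carry AMT (mg) and RATE (mg/h); observation rows
    carry DV (mg/L) with BLQ = 1 marking below-LLOQ records.
    """

    data: pd.DataFrame
    lloq: float = LLOQ_DEFAULT

    def __post_init__(self) -> None:
        missing = [c for c in TDM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"TDM table is missing columns {missing}")

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["GROUP"]))

    def n_blq(self) -> int:
        if "BLQ" not in self.data.columns:
            return 0
        return int(self.data["BLQ"].fillna(0).sum())

    def subjects(self, group: str | None = None) -> list[SubjectRecord]:
        """Assemble per-subject records, excluding below-LLOQ samples."""
        records = []
        frame = self.data if group is None else self.data[self.data["GROUP"] == group]
        for sid, grp in frame.groupby("ID", sort=False):
            doses = grp[grp["AMT"].fillna(0) > 0]
            if doses.empty:
                raise ValueError(f"subject {sid} has no dosing record")
            dose = doses.iloc[0]
            wt = float(dose["WT"])
            amt = float(dose["AMT"])
            rate = float(dose["RATE"])
            if not (wt > 0 and amt > 0 and rate > 0):
                raise ValueError(f"subject {sid} has an invalid dosing record")
            obs = grp[grp["AMT"].fillna(0) == 0]
            blq = obs["BLQ"].fillna(0).astype(bool) if "BLQ" in obs.columns else pd.Series(False, index=obs.index)
            usable = obs[~blq]
            records.append(
                SubjectRecord(
                    subject_id=str(sid),
                    group=str(dose["GROUP"]),
                    tbw=wt,
                    dose_per_kg=amt / wt,
                    infusion_duration=amt / rate,
                    times=usable["TIME"].to_numpy(dtype=float),
                    conc=usable["DV"].to_numpy(dtype=float),
                    n_blq=int(blq.sum()),
                )
            )
        if not records:
            raise ValueError(f"no subjects found (group={group!r})")
        return records


@dataclass(frozen=True)
class PopulationModel:
    """Population parameter state for one estimable parameter."""

    parameter: str = "GFR"
    typical: float = 1.31  # model-scale value at eta = 0 (population median)
    omega: float = 0.385  # between-subject SD on the log scale
    sigma: float = 0.10  # proportional residual SD

    def __post_init__(self) -> None:
        if self.parameter != "GFR":
            raise ValueError("only GFR estimation is supported")
        if self.typical <= 0:
            raise ValueError(f"typical value must be positive, got {self.typical}")
        if self.omega < 0:
            raise ValueError(f"omega must be non-negative, got {self.omega}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def population_mean(self) -> float:
        """Arithmetic-scale population mean, typical * exp(omega^2/2)."""
        return self.typical * float(np.exp(0.5 * self.omega**2))


@dataclass(frozen=True)
class IndividualEstimate:
    subject_id: str
    eta: float
    value: float  # parameter on the arithmetic scale
    var_eta: float  # curvature-based posterior variance of eta
    n_obs: int
    prior_mode: bool = False  # True when no usable observations
    converged: bool = True


def _neg_log_posterior(
    eta: float,
    subject: SubjectRecord,
    model: PopulationModel,
    base: PBPKParameters,
    mode: str,
) -> float:
    value = model.typical * float(np.exp(eta))
    params = base.with_(TBW=subject.tbw, GFR=value)
    pred = predict_conc(params, subject.regimen(), subject.times, mode=mode)
    pred = np.maximum(pred, 1e-12)
    resid = (subject.conc - pred) / (model.sigma * pred)
    nll = 0.5 * float(np.sum(resid**2)) + float(np.sum(np.log(model.sigma * pred)))
    prior = 0.5 * eta**2 / model.omega**2 if model.omega > 0 else (0.0 if eta == 0 else np.inf)
    return nll + prior


def map_individual(
    subject: SubjectRecord,
    model: PopulationModel,
    base_params: PBPKParameters,
    mode: str = "mass_conserving",
    bounds: tuple[float, float] = (-5.0, 5.0),
) -> IndividualEstimate:
    """MAP estimate of one subject's eta with curvature-based variance.

    Maximises the log-normal prior plus the proportional-error
    likelihood over eta; the reported variance is the inverse of the
    numerical second derivative of the negative log posterior at the
    mode (falling back to omega^2 when the curvature is not positive).
    With no usable observations the prior mode (eta = 0) is returned and
    flagged.
    """
    if subject.times.size == 0:
        return IndividualEstimate(
            subject_id=subject.subject_id,
            eta=0.0,
            value=model.typical,
            var_eta=model.omega**2,
            n_obs=0,
            prior_mode=True,
        )
    if model.omega == 0:
        # infinitely tight prior: the population value is the estimate
        return IndividualEstimate(
            subject_id=subject.subject_id,
            eta=0.0,
            value=model.typical,
            var_eta=0.0,
            n_obs=int(subject.times.size),
        )

    def objective(eta: float) -> float:
        return _neg_log_posterior(eta, subject, model, base_params, mode)

    result = minimize_scalar(objective, bounds=bounds, method="bounded",
                             options={"xatol": 1e-6})
    eta_hat = float(result.x)
    ok = bool(result.success)
    if not ok:
        warnings.warn(
            f"MAP optimisation did not converge for subject {subject.subject_id}: "
            f"{result.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    h = 1e-3
    curv = (objective(eta_hat + h) - 2.0 * result.fun + objective(eta_hat - h)) / h**2
    var = 1.0 / curv if curv > 0 else model.omega**2
    return IndividualEstimate(
        subject_id=subject.subject_id,
        eta=eta_hat,
        value=model.typical * float(np.exp(eta_hat)),
        var_eta=float(var),
        n_obs=int(subject.times.size),
        converged=ok,
    )


@dataclass(frozen=True)
class EstimateResult:
    """ITS output: population estimates, per-subject modes, trace."""

    model: PopulationModel
    se_typical: float  # omega / sqrt(n) on the log scale, times typical
    individuals: pd.DataFrame
    trace: list[dict] = field(repr=False)
    converged: bool = False
    n_iter: int = 0
    n_subjects: int = 0
    n_blq_excluded: int = 0
    options: dict = field(default_factory=dict, repr=False)

    @property
    def population_mean(self) -> float:
        return self.model.population_mean

    def to_json_dict(self) -> dict:
        return {
            "parameter": self.model.parameter,
            "typical": self.model.typical,
            "population_mean": self.population_mean,
            "omega": self.model.omega,
            "sigma": self.model.sigma,
            "se_typical": self.se_typical,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_subjects": self.n_subjects,
            "n_blq_excluded": self.n_blq_excluded,
            "individuals": self.individuals.to_dict(orient="records"),
            "trace": self.trace,
            "options": self.options,
        }


def its_fit(
    dataset: TDMDataset,
    initial: PopulationModel | None = None,
    base_params: PBPKParameters | None = None,
    *,
    group: str | None = None,
    mode: str = "mass_conserving",
    max_iter: int = 30,
    tol: float = 1e-3,
    estimate_sigma: bool = True,
    sigma_floor: float = 1e-4,
) -> EstimateResult:
    """Iterative two-stage population fit of GFR on one TDM dataset.

    ``base_params`` fixes every physiological parameter except GFR
    (defaults to the preterm reference subject); each subject's TBW is
    taken from the dataset.  With a single subject the between-subject
    SD is not estimable: omega stays at its initial value and the run is
    flagged.  Non-convergence after ``max_iter`` returns the best
    iterate, flagged.
    """
    initial = initial or PopulationModel()
    base = base_params or PBPKParameters.preterm()
    subjects = dataset.subjects(group=group)
    n = len(subjects)
    single_subject = n < 2
    if single_subject:
        warnings.warn(
            "between-subject SD is not estimable from a single subject; "
            "omega is kept fixed",
            RuntimeWarning,
            stacklevel=2,
        )

    model = initial
    trace: list[dict] = []
    converged = False
    estimates: list[IndividualEstimate] = []
    it = 0
    for it in range(1, max_iter + 1):
        estimates = [map_individual(s, model, base, mode=mode) for s in subjects]
        usable = [e for e in estimates if not e.prior_mode]
        if not usable:
            raise ValueError("no subject has usable observations")
        etas = np.array([e.eta for e in usable])
        vars_ = np.array([e.var_eta for e in usable])

        typical_new = model.typical * float(np.exp(np.mean(etas)))
        if single_subject:
            omega_new = model.omega
        else:
            centered = etas - np.mean(etas)
            omega_new = float(np.sqrt(np.mean(centered**2 + vars_)))
        if estimate_sigma:
            sq = []
            for subj, est in zip(subjects, estimates):
                if est.prior_mode:
                    continue
                value = model.typical * float(np.exp(est.eta))
                pred = predict_conc(
                    base.with_(TBW=subj.tbw, GFR=value), subj.regimen(), subj.times, mode=mode
                )
                sq.extend(((subj.conc - pred) / np.maximum(pred, 1e-12)) ** 2)
            sigma_new = max(float(np.sqrt(np.mean(sq))), sigma_floor)
        else:
            sigma_new = model.sigma

        # omega/sigma are judged relative to a 0.01 floor so that a
        # variance component collapsing to zero can still converge
        rel = [
            abs(typical_new - model.typical) / model.typical,
            abs(omega_new - model.omega) / max(model.omega, 1e-2),
            abs(sigma_new - model.sigma) / max(model.sigma, 1e-2),
        ]
        trace.append(
            {
                "iteration": it,
                "typical": typical_new,
                "omega": omega_new,
                "sigma": sigma_new,
                "max_rel_change": float(max(rel)),
            }
        )
        model = replace(model, typical=typical_new, omega=omega_new, sigma=sigma_new)
        if max(rel) < tol:
            converged = True
            break

    individuals = pd.DataFrame(
        [
            {
                "subject_id": e.subject_id,
                "eta": e.eta,
                "value": model.typical * float(np.exp(e.eta)),
                "var_eta": e.var_eta,
                "n_obs": e.n_obs,
                "prior_mode": e.prior_mode,
                "converged": e.converged,
            }
            for e in estimates
        ]
    )
    if not converged and max_iter > 0:
        warnings.warn(
            f"ITS did not converge within {max_iter} iterations "
            f"(last max relative change {trace[-1]['max_rel_change']:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    n_usable = int((~individuals["prior_mode"]).sum()) if len(individuals) else 0
    se = model.typical * model.omega / np.sqrt(max(n_usable, 1))
    return EstimateResult(
        model=model,
        se_typical=float(se),
        individuals=individuals,
        trace=trace,
        converged=converged,
        n_iter=it,
        n_subjects=n,
        n_blq_excluded=sum(s.n_blq for s in subjects),
        options={
            "mode": mode,
            "max_iter": max_iter,
            "tol": tol,
            "estimate_sigma": estimate_sigma,
            "group": group,
        },
    )
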