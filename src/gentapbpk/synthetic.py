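"""Synthetic TDM study generator.

Emulates the structure of the reference clinical dataset: two neonatal
subgroups (31 preterm, 16 term), demographics drawn from truncated
normals matching the published mean +/- SD and min-max per subgroup,
6 mg/kg doses infused over 0.5 h (q48h preterm, q36h term), serum
samples at 2 h and 24 h after the start of infusion, a proportional
assay error (default 10%), censoring below the 0.3 mg/L quantification
limit, and a small number of missing samples (default 3, matching the
91-of-94 sample count of the original design).

The generator records the full generating truth (per-subject parameters
and the spec itself) in a sidecar, so parameter-recovery experiments can
score estimators against known values.  It matches structure and
moments of the clinical study only; it does not attempt to reproduce
the actual patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import TDMDataset
from .model import DosingRegimen, PBPKParameters, predict_conc
from .population import DEFAULT_CV, VD_CV, lognormal_moments

__all__ = ["GroupSpec", "SyntheticStudySpec", "generate_tdm", "summarize_cohort"]


@dataclass(frozen=True)
class GroupSpec:
    """Demographics and dosing design of one subgroup."""

    label: str
    n: int
    ga_mean: float
    ga_sd: float
    ga_range: tuple[float, float]
    pna_mean: float
    pna_sd: float
    pna_range: tuple[float, float]
    tbw_mean: float
    tbw_sd: float
    tbw_range: tuple[float, float]
    dose_mean: float
    dose_sd: float
    dose_range: tuple[float, float]
    interval: float  # h, protocol dosing interval of the subgroup

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("ga", "pna", "tbw", "dose"):
            lo, hi = getattr(self, f"{name}_range")
            if not lo < hi:
                raise ValueError(f"{name}_range must satisfy min < max, got ({lo}, {hi})")


#: Published subgroup demographics (mean, SD, printed min-max).  The term
#: dose range is printed with min/max transposed; stored corrected.
PRETERM_GROUP = GroupSpec(
    label="preterm", n=31,
    ga_mean=33.7, ga_sd=1.56, ga_range=(32.0, 37.0),
    pna_mean=3.03, pna_sd=1.02, pna_range=(2.0, 7.0),
    tbw_mean=1.96, tbw_sd=0.41, tbw_range=(1.16, 3.00),
    dose_mean=5.74, dose_sd=0.80, dose_range=(4.01, 6.88),
    interval=48.0,
)
TERM_GROUP = GroupSpec(
    label="term", n=16,
    ga_mean=38.9, ga_sd=0.25, ga_range=(38.0, 39.0),
    pna_mean=2.94, pna_sd=0.85, pna_range=(2.0, 5.0),
    tbw_mean=3.09, tbw_sd=0.23, tbw_range=(2.29, 3.62),
    dose_mean=6.64, dose_sd=0.22, dose_range=(6.21, 6.99),
    interval=36.0,
)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Full design of one synthetic TDM study."""

    groups: tuple[GroupSpec, ...] = (PRETERM_GROUP, TERM_GROUP)
    dose_policy: str = "fixed"  # "fixed": protocol initial dose; "realistic": Table-style spread
    dose_fixed: float = 6.0  # mg/kg
    infusion_duration: float = 0.5  # h
    sampling_times: tuple[float, ...] = (2.0, 24.0)
    residual_cv: float = 0.10  # proportional assay error
    lloq: float = 0.3  # mg/L
    n_missing: int = 3  # samples dropped at random across the study
    vd_policy: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_policy not in ("fixed", "realistic"):
            raise ValueError(f"dose_policy must be 'fixed' or 'realistic', got {self.dose_policy!r}")
        if self.vd_policy not in ("fixed", "sampled"):
            raise ValueError(f"vd_policy must be 'fixed' or 'sampled', got {self.vd_policy!r}")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be non-negative")
        if self.n_missing < 0:
            raise ValueError("n_missing must be non-negative")

    def preterm_only(self, n: int = 31, **changes) -> "SyntheticStudySpec":
        from dataclasses import replace

        return replace(self, groups=(_with_n(PRETERM_GROUP, n),), **changes)

    def term_only(self, n: int = 16, **changes) -> "SyntheticStudySpec":
        from dataclasses import replace

        return replace(self, groups=(_with_n(TERM_GROUP, n),), **changes)


def _with_n(group: GroupSpec, n: int) -> GroupSpec:
    from dataclasses import replace

    return replace(group, n=n)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))


def generate_tdm(
    spec: SyntheticStudySpec,
    cv_map: dict[str, float] | None = None,
    mode: str = "mass_conserving",
) -> tuple[TDMDataset, dict]:
    """Generate a synthetic TDM dataset plus its generating truth.

    Per subject: demographics from truncated normals; physiological
    parameters (CO, GFR, Qk, optionally Vd) from the log-normal
    population distributions with the subject's own body weight; a true
    concentration profile from the PBPK model; observations at the
    nominal sampling times with multiplicative proportional error;
    below-LLOQ values flagged rather than reported.  Fully reproducible
    from the spec (including its seed).
    """
    cvs = dict(DEFAULT_CV if cv_map is None else cv_map)
    cvs.pop("TBW", None)  # body weight comes from the demographic model
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth_subjects: list[dict] = []

    for group in spec.groups:
        base = PBPKParameters.preterm() if group.label == "preterm" else PBPKParameters.term()
        n = group.n
        ga = _truncated_normal(rng, group.ga_mean, group.ga_sd, *group.ga_range, size=n)
        pna = _truncated_normal(rng, group.pna_mean, group.pna_sd, *group.pna_range, size=n)
        tbw = _truncated_normal(rng, group.tbw_mean, group.tbw_sd, *group.tbw_range, size=n)
        if spec.dose_policy == "fixed":
            dose = np.full(n, spec.dose_fixed)
        else:
            dose = _truncated_normal(rng, group.dose_mean, group.dose_sd, *group.dose_range, size=n)

        sampled: dict[str, np.ndarray] = {}
        for name in ("CO", "GFR", "Qk"):
            mu, sigma = lognormal_moments(getattr(base, name), cvs.get(name, 0.0))
            sampled[name] = np.exp(mu + sigma * rng.standard_normal(n))
        if spec.vd_policy == "sampled":
            mu, sigma = lognormal_moments(base.Vd, VD_CV[group.label])
            sampled["Vd"] = np.exp(mu + sigma * rng.standard_normal(n))
        else:
            sampled["Vd"] = np.full(n, base.Vd)

        eps = rng.standard_normal((n, len(spec.sampling_times)))
        for i in range(n):
            sid = f"{group.label}-{i + 1:03d}"
            params = base.with_(
                TBW=float(tbw[i]),
                CO=float(sampled["CO"][i]),
                GFR=float(sampled["GFR"][i]),
                Qk=float(sampled["Qk"][i]),
                Vd=float(sampled["Vd"][i]),
            )
            regimen = DosingRegimen(
                dose_per_kg=float(dose[i]),
                interval=group.interval,
                infusion_duration=spec.infusion_duration,
                n_doses=1,
            )
            pred = predict_conc(params, regimen, spec.sampling_times, mode=mode)
            obs = pred * (1.0 + spec.residual_cv * eps[i])
            obs = np.maximum(obs, 0.0)
            amt = regimen.dose_mg(params.TBW)
            common = {
                "ID": sid, "WT": round(float(tbw[i]), 6), "GROUP": group.label,
                "GA": round(float(ga[i]), 3), "PNA": round(float(pna[i]), 3),
            }
            rows.append(
                {**common, "TIME": 0.0, "DV": np.nan, "AMT": amt,
                 "RATE": amt / spec.infusion_duration, "BLQ": 0}
            )
            for t, value, true_value in zip(spec.sampling_times, obs, pred):
                blq = value < spec.lloq
                rows.append(
                    {**common, "TIME": float(t),
                     "DV": np.nan if blq else float(value),
                     "AMT": 0.0, "RATE": 0.0, "BLQ": int(blq)}
                )
            truth_subjects.append(
                {
                    "subject_id": sid, "group": group.label,
                    "TBW": float(tbw[i]), "GA": float(ga[i]), "PNA": float(pna[i]),
                    "dose_per_kg": float(dose[i]),
                    "CO": float(sampled["CO"][i]), "GFR": float(sampled["GFR"][i]),
                    "Qk": float(sampled["Qk"][i]), "Vd": float(sampled["Vd"][i]),
                    "true_conc": [float(v) for v in pred],
                }
            )

    frame = pd.DataFrame(rows)
    if spec.n_missing > 0:
        obs_idx = frame.index[frame["AMT"] == 0.0].to_numpy()
        drop = rng.choice(obs_idx, size=min(spec.n_missing, obs_idx.size), replace=False)
        frame = frame.drop(index=drop).reset_index(drop=True)

    truth = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "groups"},
            "groups": [asdict(g) for g in spec.groups],
        },
        "population_means": {
            g.label: {"GFR": (PBPKParameters.preterm() if g.label == "preterm" else PBPKParameters.term()).GFR}
            for g in spec.groups
        },
        "subjects": truth_subjects,
    }
    return TDMDataset(data=frame, lloq=spec.lloq), truth


def summarize_cohort(dataset: TDMDataset) -> pd.DataFrame:
    """Per-subgroup mean +/- SD (min-max) demographic and level summary.

    One row per subgroup and variable (GA, PNA, TBW, dose per kg, and
    quantifiable concentration at each nominal sampling time), mirroring
    the layout of a clinical baseline-characteristics table.
    """
    frame = dataset.data
    if len(frame) == 0:
        raise ValueError("empty dataset")
    records = []
    for group in dataset.groups():
        sub = frame[frame["GROUP"] == group]
        doses = sub[sub["AMT"].fillna(0) > 0]
        per_subject = doses.drop_duplicates("ID")
        variables = {
            "GA_weeks": per_subject["GA"] if "GA" in per_subject else None,
            "PNA_days": per_subject["PNA"] if "PNA" in per_subject else None,
            "TBW_kg": per_subject["WT"],
            "dose_mg_per_kg": per_subject["AMT"] / per_subject["WT"],
        }
        obs = sub[sub["AMT"].fillna(0) == 0]
        quantifiable = obs if "BLQ" not in obs.columns else obs[obs["BLQ"].fillna(0) == 0]
        for t in sorted(quantifiable["TIME"].unique()):
            variables[f"conc_{t:g}h_mg_L"] = quantifiable.loc[quantifiable["TIME"] == t, "DV"]
        for name, values in variables.items():
            if values is None or len(values) == 0:
                continue
            arr = values.to_numpy(dtype=float)
            records.append(
                {
                    "group": group,
                    "variable": name,
                    "n": arr.size,
                    "mean": float(np.mean(arr)),
                    "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
                    "min": float(np.min(arr)),
                    "max": float(np.max(arr)),
                }
            )
    return pd.DataFrame.from_records(records)
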