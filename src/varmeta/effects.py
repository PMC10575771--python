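"""Per-study effect sizes: lnCVR, lnVR, Hedges' g, and the mean-SD diagnostic.

Variability measures
--------------------
The log variability ratio compares arm standard deviations,

    lnVR = ln(S_p / S_c) + 1/(2(n_p - 1)) - 1/(2(n_c - 1)),

where the second and third terms correct the small-sample bias of ln(S).
Because in many natural systems the SD scales with the mean, the primary
variability measure adjusts for the means — the log coefficient of
variation ratio:

    lnCVR = ln( (S_p / x̄_p) / (S_c / x̄_c) ) + 1/(2(n_p - 1)) - 1/(2(n_c - 1)).

Positive values mean relatively greater variability in patients.  Sampling
variances use the standard independent-groups approximations (no mean-SD
correlation term):

    var(lnVR)  = 1/(2(n_p - 1)) + 1/(2(n_c - 1))
    var(lnCVR) = S_p^2/(n_p x̄_p^2) + 1/(2(n_p - 1))
               + S_c^2/(n_c x̄_c^2) + 1/(2(n_c - 1)).

The lnCVR/lnVR variance formulas are an analysis assumption (they are not
uniquely fixed by the measures themselves); they are flagged as such in the
serialised metadata.

Magnitude
---------
Hedges' g is Cohen's d shrunk by J = 1 - 3/(4 df - 1), df = n_p + n_c - 2,
with the usual large-sample variance J^2 [ N/(n_p n_c) + d^2/(2N) ]; an
alternative using df instead of N in the d^2 term is available behind the
``var_method`` flag.  Negative g means lower levels in patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from varmeta.data import GroupSummary, StudyRecord

__all__ = ["EffectSize", "ln_cvr", "ln_vr", "hedges_g", "weighted_pearson",
           "effects_from_record", "effect_table", "MEASURES"]

MEASURES = ("lnCVR", "lnVR", "g")


@dataclass(frozen=True)
class EffectSize:
    measure: str
    estimate: float
    variance: float
    study_id: str = ""
    cohort_id: str = ""
    region: str = ""
    metabolite: str = ""
    medication_status: str = ""
    df: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.estimate):
            raise ValueError(f"non-finite estimate for {self.study_id or '<anon>'}")
        if not (self.variance > 0):
            raise ValueError(f"non-positive variance for {self.study_id or '<anon>'}")


def _bias_terms(n_p: float, n_c: float) -> float:
    return 1.0 / (2.0 * (n_p - 1.0)) - 1.0 / (2.0 * (n_c - 1.0))


def ln_cvr(patient: GroupSummary, control: GroupSummary, **meta) -> EffectSize:
    """Bias-corrected log coefficient of variation ratio (patient vs control)."""
    if patient.mean <= 0 or control.mean <= 0:
        raise ValueError(f"non-positive mean in record {meta.get('study_id', '<anon>')}")
    est = (math.log((patient.sd / patient.mean) / (control.sd / control.mean))
           + _bias_terms(patient.n, control.n))
    var = (patient.sd ** 2 / (patient.n * patient.mean ** 2)
           + 1.0 / (2.0 * (patient.n - 1.0))
           + control.sd ** 2 / (control.n * control.mean ** 2)
           + 1.0 / (2.0 * (control.n - 1.0)))
    return EffectSize("lnCVR", est, var, **meta)


def ln_vr(patient: GroupSummary, control: GroupSummary, **meta) -> EffectSize:
    """Bias-corrected log variability (SD) ratio, unadjusted for means."""
    est = math.log(patient.sd / control.sd) + _bias_terms(patient.n, control.n)
    var = 1.0 / (2.0 * (patient.n - 1.0)) + 1.0 / (2.0 * (control.n - 1.0))
    return EffectSize("lnVR", est, var, **meta)


def hedges_g(patient: GroupSummary, control: GroupSummary,
             var_method: str = "large_sample", **meta) -> EffectSize:
    """Hedges' g standardised mean difference (patient minus control)."""
    n_p, n_c = patient.n, control.n
    df = n_p + n_c - 2.0
    s2 = ((n_p - 1.0) * patient.sd ** 2 + (n_c - 1.0) * control.sd ** 2) / df
    if s2 <= 0:
        raise ValueError(f"zero pooled SD in record {meta.get('study_id', '<anon>')}")
    d = (patient.mean - control.mean) / math.sqrt(s2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    N = n_p + n_c
    if var_method == "large_sample":
        var = J ** 2 * (N / (n_p * n_c) + d ** 2 / (2.0 * N))
    elif var_method == "df":
        var = J ** 2 * (N / (n_p * n_c) + d ** 2 / (2.0 * df))
    else:
        raise ValueError(f"unknown var_method {var_method!r}")
    return EffectSize("g", g, var, df=df, **meta)


def weighted_pearson(x: Sequence[float], y: Sequence[float],
                     w: Sequence[float]) -> float:
    """Weighted Pearson correlation with weights normalised to sum one."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance")
    return float(cov / math.sqrt(vx * vy))


def effects_from_record(record: StudyRecord,
                        measures: Iterable[str] = MEASURES,
                        var_method: str = "large_sample") -> list[EffectSize]:
    meta = dict(study_id=record.study_id, cohort_id=record.cohort_id,
                region=record.region, metabolite=record.metabolite,
                medication_status=record.medication_status)
    out = []
    for m in measures:
        if m == "lnCVR":
            out.append(ln_cvr(record.patient, record.control, **meta))
        elif m == "lnVR":
            out.append(ln_vr(record.patient, record.control, **meta))
        elif m == "g":
            out.append(hedges_g(record.patient, record.control,
                                var_method=var_method, **meta))
        else:
            raise ValueError(f"unknown measure {m!r}")
    return out


def effect_table(records: Iterable[StudyRecord],
                 measures: Iterable[str] = MEASURES,
                 var_method: str = "large_sample") -> pd.DataFrame:
    """One row per cohort x region x metabolite x measure."""
    rows = []
    for rec in records:
        for es in effects_from_record(rec, measures, var_method):
            rows.append({
                "study_id": es.study_id, "cohort_id": es.cohort_id,
                "region": es.region, "metabolite": es.metabolite,
                "medication_status": es.medication_status,
                "measure": es.measure, "estimate": es.estimate,
                "variance": es.variance, "df": es.df,
            })
    return pd.DataFrame(rows)
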