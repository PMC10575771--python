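"""Synthetic study-level tables and individual-level samples with known truth.

The generator emulates the statistical structure assumed by the analysis:
normally distributed metabolite levels within each arm, a true per-study
effect drawn around the population value with between-study SD tau, and
linear moderator effects on the study-level true effect.  Group summaries
are the sample mean/SD/n of actually simulated individuals, so summary
noise has the correct finite-sample behaviour.  Individual-level patient
data can instead be drawn from a one- or two-component Gaussian mixture to
exercise the modality analysis; controls stay unimodal.

Default configuration: 60 studies of 15-60 participants per arm, control
coefficient of variation 0.15 around a mean of 10 institutional units,
true lnCVR 0.15 and true Hedges'-type shift -0.15 with between-study SD
tau = 0.05 — the effect-size regime of frontal-cortex glutamate
case-control comparisons.

Reproducibility: one integer seed governs everything; study i uses the
deterministic substream ``default_rng([seed, i])`` (counter-based), so
enlarging k_studies leaves earlier studies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from varmeta.data import MODERATORS

__all__ = ["SynthConfig", "gen_study_level", "gen_individual"]

#: moderator sampling distributions (mean, sd) typical of case-control
#: 1H-MRS study populations
DEFAULT_MODERATOR_DISTRIBUTIONS = {
    "mean_age": (31.0, 6.0),
    "prop_male": (0.66, 0.10),
    "panss_total": (75.0, 15.0),
    "cpz": (400.0, 150.0),
}


@dataclass(frozen=True)
class SynthConfig:
    k_studies: int = 60
    n_range: tuple[int, int] = (15, 60)       # per-arm sample size bounds
    true_smd: float = -0.15                   # delta, Hedges'-g scale
    true_log_cv_ratio: float = 0.15           # phi, lnCVR scale
    tau: float = 0.05                         # between-study SD of true effects
    moderator_effects: Mapping[str, float] = field(default_factory=dict)
    moderator_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODERATOR_DISTRIBUTIONS))
    base_cv_control: float = 0.15
    base_mean_control: float = 10.0
    #: SD of log control mean across studies; emulates between-study
    #: differences in acquisition and quantification scale.  The scale-free
    #: effect sizes are invariant to it, but it gives the study-level table a
    #: realistic mean-SD scaling relationship.
    mean_log_sd: float = 0.3
    mixture_components: int = 1
    mixture_separation: float = 3.0           # in control-SD units
    mixture_proportion: float = 0.5
    region: str = "MFC"
    metabolite: str = "glutamate"
    seed: int = 0

    def __post_init__(self):
        if self.n_range[0] < 5:
            raise ValueError("minimum per-arm n is 5")
        if self.base_cv_control <= 0 or self.base_mean_control <= 0:
            raise ValueError("base control mean and CV must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.mixture_components not in (1, 2):
            raise ValueError("mixture_components must be 1 or 2")
        if not (0.0 < self.mixture_proportion < 1.0):
            raise ValueError("mixture_proportion must be in (0, 1)")
        for name in self.moderator_effects:
            if name not in MODERATORS:
                raise ValueError(f"unknown moderator {name!r}")


def _study_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng([seed, i])


def _draw_moderators(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    mods = {}
    for name, (mu, sd) in cfg.moderator_distributions.items():
        val = rng.normal(mu, sd)
        if name == "prop_male":
            val = float(np.clip(val, 0.0, 1.0))
        mods[name] = float(val)
    return mods


def gen_study_level(config: SynthConfig, return_samples: bool = False):
    """Generate a study-level summary table in the ingest schema.

    Returns ``(table, truth)`` where ``truth`` records the per-study true
    effects and population parameters, or ``(table, truth, samples)`` with
    the raw simulated individuals when ``return_samples`` is set.

    For study i the true effects are

        theta_i = phi  + sum_m beta_m (m_i - mean_m) + N(0, tau^2)   (lnCVR)
        delta_i = delta + sum_m beta_m (m_i - mean_m) + N(0, tau^2)  (SMD)

    (moderator effects enter both, centred so the population values are
    preserved).  Patient individuals are N(mu_p, (CV_p mu_p)^2) with
    CV_p = CV_c exp(theta_i) and mu_p = mu_c + delta_i sigma_c.
    """
    cfg = config
    rows, truth_rows, samples = [], [], {}
    for i in range(cfg.k_studies):
        rng = _study_rng(cfg.seed, i)
        mods = _draw_moderators(cfg, rng)
        mod_shift = 0.0
        for name, beta in cfg.moderator_effects.items():
            centre = cfg.moderator_distributions.get(name, (0.0, 1.0))[0]
            mod_shift += beta * (mods.get(name, centre) - centre)
        theta = cfg.true_log_cv_ratio + mod_shift + rng.normal(0.0, cfg.tau)
        delta = cfg.true_smd + mod_shift + rng.normal(0.0, cfg.tau)
        n_p = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        n_c = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        mu_c = cfg.base_mean_control * float(np.exp(rng.normal(0.0, cfg.mean_log_sd)))
        sd_c = cfg.base_cv_control * mu_c
        cv_p = cfg.base_cv_control * np.exp(theta)
        mu_p = mu_c + delta * sd_c
        if mu_p <= 0:
            raise ValueError(
                f"config implies non-positive patient mean ({mu_p:.3g}) in study {i}")
        sd_p = cv_p * mu_p
        xs_c = rng.normal(mu_c, sd_c, n_c)
        xs_p = rng.normal(mu_p, sd_p, n_p)
        sid = f"synth{i + 1:03d}"
        row = {
            "study_id": sid, "cohort_id": sid, "timepoint": 1,
            "region": cfg.region, "metabolite": cfg.metabolite,
            "medication_status": "medicated" if i % 2 else "antipsychotic_naive",
            "n_patients": n_p, "mean_patients": float(xs_p.mean()),
            "sd_patients": float(xs_p.std(ddof=1)),
            "n_controls": n_c, "mean_controls": float(xs_c.mean()),
            "sd_controls": float(xs_c.std(ddof=1)),
            "n_clinical_groups": 1, "acquisition": "standard",
            "reference_scheme": "cr_scaled",
        }
        row.update(mods)
        rows.append(row)
        truth_rows.append({
            "study_id": sid, "theta_lncvr": float(theta), "delta_smd": float(delta),
            "mu_control": mu_c, "sd_control": sd_c, "mu_patient": float(mu_p),
            "sd_patient": float(sd_p), "n_patients": n_p, "n_controls": n_c,
            **{f"mod_{k}": v for k, v in mods.items()},
        })
        if return_samples:
            samples[sid] = {"patients": xs_p, "controls": xs_c}
    table = pd.DataFrame(rows)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()
                   if not isinstance(v, Mapping)},
        "moderator_effects": dict(cfg.moderator_effects),
        "studies": truth_rows,
    }
    if return_samples:
        return table, truth, samples
    return table, truth


def gen_individual(config: SynthConfig) -> pd.DataFrame:
    """Long-format individual-level table for the modality analysis.

    Patients are drawn from ``mixture_components`` Gaussian components with
    means mu_c -/+ separation * sigma_c / 2 (mixing proportion on the upper
    component); controls are always unimodal N(mu_c, sigma_c^2).  Columns
    match the modality input schema.
    """
    cfg = config
    rows = []
    for i in range(cfg.k_studies):
        rng = _study_rng(cfg.seed, i)
        n_p = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        n_c = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        mu_c = cfg.base_mean_control * float(np.exp(rng.normal(0.0, cfg.mean_log_sd)))
        sd_c = cfg.base_cv_control * mu_c
        sid = f"synth{i + 1:03d}"
        if cfg.mixture_components == 2:
            half = cfg.mixture_separation * sd_c / 2.0
            comp = rng.random(n_p) < cfg.mixture_proportion
            vals_p = np.where(comp,
                              rng.normal(mu_c + half, sd_c, n_p),
                              rng.normal(mu_c - half, sd_c, n_p))
        else:
            vals_p = rng.normal(mu_c, sd_c, n_p)
        vals_c = rng.normal(mu_c, sd_c, n_c)
        for grp, vals in (("patient", vals_p), ("control", vals_c)):
            for j, v in enumerate(vals):
                rows.append({
                    "study_id": sid, "subject_id": f"{sid}_{grp[0]}{j + 1:03d}",
                    "group": grp, "metabolite": cfg.metabolite,
                    "reference_scheme": "cr_scaled", "value": float(v),
                })
    return pd.DataFrame(rows)
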