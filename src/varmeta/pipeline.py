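"""Orchestration: full analysis over region x metabolite x measure cells.

For every region x metabolite with at least two studies the pipeline pools
lnCVR, lnVR and Hedges' g for all patients and separately for the
antipsychotic-naive and medicated sensitivity subsets, Wald-compares the
two subsets where both are estimable, runs moderator meta-regressions
(mean age, proportion male, PANSS total, CPZ dose), follows significant
results up with dispersion (age SD, PANSS SD) and data-quality (SNR, FWHM
ratio) regressions, and controls the false discovery rate per measure x
metabolite x subset family across regions.  Every skipped cell is logged
with its reason; nothing disappears silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from varmeta import data as _data
from varmeta.data import IngestResult, StudyRecord, read_study_table
from varmeta.effects import MEASURES, effect_table, weighted_pearson
from varmeta.meta import (
    ConvergenceError, MetaRegressionResult, PooledResult, WaldComparison,
    bh_fdr, compare_subgroups, meta_regress, pool_random_effects,
)
from varmeta.modality import DipResult, pool_and_test

__all__ = ["AnalysisConfig", "ResultSet", "run_full_analysis",
           "export_forest_tables"]

logger = logging.getLogger("varmeta")

PRIMARY_MODERATORS = ("mean_age", "prop_male", "panss_total", "cpz")
FOLLOWUP_SD = {"mean_age": "age_sd", "panss_total": "panss_total_sd"}
QUALITY_MODERATORS = ("snr_ratio", "fwhm_ratio")
SUBSETS = ("all", "antipsychotic_naive", "medicated")


@dataclass(frozen=True)
class AnalysisConfig:
    estimator: str = "reml"            # or "dl"
    min_k: int = 5                     # minimum studies for a meta-regression
    fdr_q: float = 0.10
    fdr_family: str = "measure_metabolite_subset"   # family spans regions
    dip_scheme: str = "divide_by_mean"              # "subtract_mean" also run
    dip_n_sim: int = 2000
    control_n_mode: str = "fractional"
    hedges_var_method: str = "large_sample"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ResultSet:
    pooled: list[PooledResult] = field(default_factory=list)
    regressions: list[MetaRegressionResult] = field(default_factory=list)
    subgroup_tests: list[WaldComparison] = field(default_factory=list)
    dip: list[DipResult] = field(default_factory=list)
    fdr_flags: dict = field(default_factory=dict)   # family label -> details
    mean_sd_correlation: float | None = None
    skipped: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def pooled_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.pooled])

    def regression_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.regressions])

    def to_dict(self) -> dict:
        return {
            "pooled": [asdict(p) for p in self.pooled],
            "regressions": [asdict(r) for r in self.regressions],
            "subgroup_tests": [asdict(w) for w in self.subgroup_tests],
            "dip": [asdict(d) for d in self.dip],
            "fdr_flags": self.fdr_flags,
            "mean_sd_correlation": self.mean_sd_correlation,
            "skipped": self.skipped,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonable)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not serialisable: {type(obj)}")


def _ingest(study_table, control_n_mode) -> tuple[list[StudyRecord], dict]:
    if isinstance(study_table, IngestResult):
        return study_table.records, {"input": "IngestResult",
                                     "digest": "n/a"}
    if isinstance(study_table, (str, Path)):
        digest = hashlib.sha256(Path(study_table).read_bytes()).hexdigest()[:16]
        res = read_study_table(study_table, control_n_mode=control_n_mode)
        for _, rej in res.rejects.iterrows():
            logger.info("ingest reject row=%s study=%s: %s",
                        rej["row"], rej["study_id"], rej["reason"])
        return res.records, {"input": str(study_table), "digest": digest,
                             "ingest_summary": res.summary}
    if isinstance(study_table, pd.DataFrame):
        import io
        buf = io.StringIO()
        study_table.to_csv(buf, index=False)
        digest = hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]
        import tempfile, os
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            study_table.to_csv(fh, index=False)
            tmp = fh.name
        try:
            res = read_study_table(tmp, control_n_mode=control_n_mode)
        finally:
            os.unlink(tmp)
        return res.records, {"input": "DataFrame", "digest": digest,
                             "ingest_summary": res.summary}
    records = list(study_table)
    return records, {"input": "records", "digest": "n/a"}


def _subset_effects(df: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return df
    return df[df["medication_status"] == subset]


def run_full_analysis(study_table, config: AnalysisConfig | str | Path | None = None,
                      individual_samples: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
                      ) -> ResultSet:
    """Run the complete meta-analysis on a study-level table.

    Parameters
    ----------
    study_table : path, DataFrame, IngestResult or iterable of StudyRecord
    config : AnalysisConfig or path to a YAML file
    individual_samples : optional individual-level patient data for the
        modality analysis — either a long-format DataFrame (schema of
        :func:`varmeta.simulate.gen_individual`) or a mapping
        study_id -> values.
    """
    if config is None:
        config = AnalysisConfig()
    elif isinstance(config, (str, Path)):
        config = AnalysisConfig.from_yaml(config)

    records, prov_in = _ingest(study_table, config.control_n_mode)
    if not records:
        raise ValueError("no valid study records to analyse")
    eff = effect_table(records, var_method=config.hedges_var_method)
    rec_frame = _data.records_to_frame(records)

    rs = ResultSet()
    rs.provenance = {
        "package_version": __import__("varmeta").__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "lncvr_variance": "independent-groups approximation, no mean-SD correlation term",
        **prov_in,
    }

    def skip(**why):
        rs.skipped.append(why)
        logger.info("skip: %s", why)

    # ---------------- pooling per region x metabolite x measure x subset
    for (region, metab), cell in eff.groupby(["region", "metabolite"], sort=True):
        for measure in MEASURES:
            mcell = cell[cell["measure"] == measure]
            pooled_by_subset = {}
            for subset in SUBSETS:
                sub = _subset_effects(mcell, subset)
                if len(sub) < 2:
                    skip(cell=f"{region}/{metab}/{measure}/{subset}",
                         reason=f"k={len(sub)} < 2")
                    continue
                try:
                    pr = pool_random_effects(
                        sub, method=config.estimator, measure=measure,
                        region=region, metabolite=metab, subset=subset)
                except ConvergenceError as exc:
                    skip(cell=f"{region}/{metab}/{measure}/{subset}",
                         reason=f"convergence: {exc}")
                    continue
                pooled_by_subset[subset] = pr
                rs.pooled.append(pr)
                logger.info("pooled %s/%s/%s/%s k=%d est=%.4f p=%.3g",
                            region, metab, measure, subset, pr.k,
                            pr.estimate, pr.p_value)
            a = pooled_by_subset.get("antipsychotic_naive")
            b = pooled_by_subset.get("medicated")
            if a is not None and b is not None:
                wc = compare_subgroups(
                    a, b, label=f"{region}/{metab}/{measure}:naive_vs_medicated")
                rs.subgroup_tests.append(wc)

    # ---------------- FDR per measure x metabolite x subset across regions
    pooled_df = rs.pooled_frame()
    if len(pooled_df):
        for (measure, metab, subset), fam in pooled_df.groupby(
                ["measure", "metabolite", "subset"], sort=True):
            flags = bh_fdr(fam["p_value"].to_numpy(), q=config.fdr_q)
            key = f"{measure}|{metab}|{subset}"
            rs.fdr_flags[key] = {
                "regions": list(fam["region"]),
                "p_values": [float(p) for p in fam["p_value"]],
                "reject": [bool(f) for f in flags],
                "q": config.fdr_q,
            }

    # ---------------- meta-regressions (primary + follow-ups)
    def regress_cell(mcell, region, metab, measure, moderator):
        mask = []
        vals = []
        for _, row in mcell.iterrows():
            rec = next(r for r in records
                       if r.cohort_id == row["cohort_id"]
                       and r.region == region and r.metabolite == metab)
            v = rec.moderators.get(moderator)
            mask.append(v is not None)
            vals.append(v if v is not None else np.nan)
        sub = mcell[np.array(mask, bool)]
        mod = np.array(vals, float)[np.array(mask, bool)]
        label = f"{region}/{metab}/{measure}~{moderator}"
        if len(sub) < config.min_k:
            skip(cell=label, reason=f"k={len(sub)} < min_k={config.min_k}")
            return None
        if len(sub) and np.ptp(mod) == 0:
            skip(cell=label, reason="constant moderator")
            return None
        try:
            mr = meta_regress(sub, mod, name=moderator,
                              method=config.estimator, min_k=config.min_k)
        except (ValueError, ConvergenceError) as exc:
            skip(cell=label, reason=str(exc))
            return None
        mr.measure = measure
        mr.region = region
        mr.metabolite = metab
        rs.regressions.append(mr)
        logger.info("metareg %s slope=%.4g p=%.3g k=%d",
                    label, mr.slope, mr.p_value, mr.k)
        return mr

    for (region, metab), cell in eff.groupby(["region", "metabolite"], sort=True):
        for measure in ("lnCVR", "g"):
            mcell = cell[cell["measure"] == measure]
            for moderator in PRIMARY_MODERATORS:
                mr = regress_cell(mcell, region, metab, measure, moderator)
                # dispersion follow-up for significant primary regressions
                if mr is not None and mr.p_value < 0.05 and moderator in FOLLOWUP_SD:
                    regress_cell(mcell, region, metab, measure,
                                 FOLLOWUP_SD[moderator])
            # data-quality follow-ups where the primary CVR pooling was
            # FDR-significant in this region
            if measure == "lnCVR":
                key = f"lnCVR|{metab}|all"
                fam = rs.fdr_flags.get(key)
                if fam and region in fam["regions"]:
                    if fam["reject"][fam["regions"].index(region)]:
                        for moderator in QUALITY_MODERATORS:
                            regress_cell(mcell, region, metab, "lnCVR", moderator)

    # ---------------- weighted mean-SD diagnostic (both arms, weight = n_p+n_c)
    if len(rec_frame) >= 3:
        means = np.concatenate([rec_frame["mean_patients"], rec_frame["mean_controls"]])
        sds = np.concatenate([rec_frame["sd_patients"], rec_frame["sd_controls"]])
        wts = np.concatenate([rec_frame["n_patients"] + rec_frame["n_controls"]] * 2)
        try:
            rs.mean_sd_correlation = weighted_pearson(means, sds, wts)
        except ValueError as exc:
            skip(cell="mean_sd_correlation", reason=str(exc))

    # ---------------- modality analysis on individual-level data
    if individual_samples is not None:
        if isinstance(individual_samples, pd.DataFrame):
            patients = individual_samples[
                individual_samples.get("group", "patient") == "patient"]
            groups = {sid: g["value"].to_numpy()
                      for sid, g in patients.groupby("study_id")}
        else:
            groups = {k: np.asarray(v, float)
                      for k, v in individual_samples.items()}
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if groups:
            ids = sorted(groups)
            schemes = [config.dip_scheme]
            other = ("subtract_mean" if config.dip_scheme == "divide_by_mean"
                     else "divide_by_mean")
            schemes.append(other)
            for scheme in schemes:
                pooled, per_study = pool_and_test(
                    [groups[i] for i in ids], scheme=scheme,
                    n_sim=config.dip_n_sim, seed=config.seed,
                    study_ids=ids)
                tag = "" if scheme == config.dip_scheme else f" [{scheme}]"
                rs.dip.append(DipResult(**{**asdict(pooled),
                                           "study_id": f"pooled ({scheme})"}))
                if scheme == config.dip_scheme:
                    rs.dip.extend(per_study)
                logger.info("dip pooled%s D=%.4f p=%.3g", tag, pooled.dip,
                            pooled.p_value)

    return rs


def export_forest_tables(results: ResultSet, out_dir: str | Path) -> list[Path]:
    """Write per-measure forest tables (TSV) plus the full JSON result set."""
    if not results.pooled:
        raise ValueError("empty result set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    df = results.pooled_frame()
    cols = ["region", "metabolite", "subset", "k", "estimate", "ci_low",
            "ci_high", "p_value", "i2"]
    for measure, sub in df.groupby("measure", sort=True):
        path = out / f"forest_{measure}.tsv"
        sub[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)
    if len(results.regressions):
        path = out / "meta_regressions.tsv"
        results.regression_frame().drop(columns=["study_ids"]).to_csv(
            path, sep="\t", index=False, float_format="%.6f")
        written.append(path)
    path = out / "results.json"
    results.to_json(path)
    written.append(path)
    return written
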