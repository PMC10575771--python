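"""Ingest: read, validate, harmonise and filter study-level summary tables.

The unit of analysis is one clinical cohort x brain region x metabolite with
a patient and a control arm, each summarised by (mean, SD, n).  Region labels
are harmonised through an explicit, versioned synonym table; free-text labels
that are not in the table raise rather than being guessed into a bucket.
Control arms shared between several clinical groups of one study have their
n divided by the number of groups (fractional by default, since the
small-sample bias terms 1/(2(n-1)) are continuous in n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REGIONS", "METABOLITES", "MEDICATION_STATUSES", "ACQUISITIONS",
    "REFERENCE_SCHEMES", "MODERATORS", "REGION_SYNONYMS",
    "GroupSummary", "StudyRecord", "IngestResult",
    "read_study_table", "write_study_table", "assign_region",
    "rescale_metabolite", "adjust_control_n", "load_schema",
]

REGIONS = (
    "MFC", "DLPFC", "frontal_white_matter", "thalamus", "temporal_lobe",
    "basal_ganglia",
)
METABOLITES = ("glutamate", "glutamine", "Glx")
MEDICATION_STATUSES = ("antipsychotic_naive", "medicated", "mixed")
ACQUISITIONS = ("standard", "j_edited", "epsi")
REFERENCE_SCHEMES = ("cr_scaled", "csf_corrected", "other")
MODERATORS = (
    "mean_age", "age_sd", "prop_male", "panss_total", "panss_total_sd",
    "cpz", "snr_ratio", "fwhm_ratio",
)

#: Versioned voxel-label synonym table (v1).  Keys are normalised labels
#: (lower case, single spaces); values are canonical regions.  The medial
#: frontal category deliberately absorbs anterior cingulate voxels, and the
#: temporal category absorbs hippocampus, mirroring the usual 1H-MRS
#: region-of-interest groupings.
REGION_SYNONYMS_VERSION = 1
REGION_SYNONYMS: dict[str, str] = {
    "mfc": "MFC",
    "medial frontal cortex": "MFC",
    "medial prefrontal cortex": "MFC",
    "mpfc": "MFC",
    "anterior cingulate cortex": "MFC",
    "anterior cingulate": "MFC",
    "acc": "MFC",
    "pregenual anterior cingulate": "MFC",
    "dorsal anterior cingulate": "MFC",
    "rostral anterior cingulate": "MFC",
    "dlpfc": "DLPFC",
    "dorsolateral prefrontal cortex": "DLPFC",
    "left dorsolateral prefrontal cortex": "DLPFC",
    "right dorsolateral prefrontal cortex": "DLPFC",
    "frontal white matter": "frontal_white_matter",
    "fwm": "frontal_white_matter",
    "frontal wm": "frontal_white_matter",
    "centrum semiovale": "frontal_white_matter",
    "thalamus": "thalamus",
    "left thalamus": "thalamus",
    "right thalamus": "thalamus",
    "mediodorsal thalamus": "thalamus",
    "temporal lobe": "temporal_lobe",
    "temporal cortex": "temporal_lobe",
    "superior temporal gyrus": "temporal_lobe",
    "stg": "temporal_lobe",
    "hippocampus": "temporal_lobe",
    "medial temporal lobe": "temporal_lobe",
    "basal ganglia": "basal_ganglia",
    "striatum": "basal_ganglia",
    "dorsal striatum": "basal_ganglia",
    "associative striatum": "basal_ganglia",
    "limbic striatum": "basal_ganglia",
    "caudate": "basal_ganglia",
    "putamen": "basal_ganglia",
    "globus pallidus": "basal_ganglia",
    "substantia nigra": "basal_ganglia",
}

_MANDATORY = (
    "study_id", "region", "metabolite",
    "n_patients", "mean_patients", "sd_patients",
    "n_controls", "mean_controls", "sd_controls",
)


def load_schema() -> dict:
    """Return the shipped column dictionary (``schema.yaml``)."""
    path = Path(__file__).with_name("schema.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _norm_label(label: str) -> str:
    return " ".join(str(label).strip().lower().replace("_", " ").replace("-", " ").split())


def assign_region(voxel_label: str) -> str:
    """Map a free-text voxel label to one of the six canonical regions.

    The mapping is deterministic and total on the shipped synonym table;
    anything else raises a ``KeyError`` listing the table, so unknown voxel
    placements are curated explicitly instead of being guessed.
    """
    if not str(voxel_label).strip():
        raise ValueError("empty voxel label")
    key = _norm_label(voxel_label)
    if key in REGION_SYNONYMS:
        return REGION_SYNONYMS[key]
    # canonical names pass through (case-insensitive)
    for region in REGIONS:
        if key == _norm_label(region):
            return region
    known = sorted(REGION_SYNONYMS)
    raise KeyError(
        f"unknown voxel label {voxel_label!r} (synonym table v{REGION_SYNONYMS_VERSION}); "
        f"known labels: {known}"
    )


def adjust_control_n(n_controls: float, n_clinical_groups: int,
                     mode: str = "fractional") -> float:
    """Effective control n when one control arm serves several cohorts.

    ``fractional`` (default) keeps n_controls / n_clinical_groups exactly;
    ``rounded`` rounds half-down to an integer, never below 2.  A result
    below 2 makes the 1/(2(n-1)) bias terms meaningless and the caller is
    expected to flag the record unusable.
    """
    if n_controls < 1 or n_clinical_groups < 1:
        raise ValueError("n_controls and n_clinical_groups must be >= 1")
    eff = n_controls / n_clinical_groups
    if mode == "fractional":
        return eff
    if mode == "rounded":
        if eff < 2:
            return eff
        return float(max(2, math.ceil(eff - 0.5)))
    raise ValueError(f"unknown mode {mode!r} (use 'fractional' or 'rounded')")


def rescale_metabolite(mean: float, sd: float, factor: float,
                       acquisition: str) -> tuple[float, float]:
    """Multiply mean and SD of a j-edited / EPSI measurement by a common factor.

    Factors of 1000 or 100000 bring those acquisition schemes onto a scale
    numerically comparable with standard acquisitions.  lnCVR, lnVR and
    Hedges' g are invariant to the rescaling (they are scale-free), so this
    affects presentation only.
    """
    if acquisition not in ("j_edited", "epsi"):
        raise ValueError(
            f"rescaling applies to j_edited/epsi acquisitions only, got {acquisition!r}"
        )
    if float(factor) not in (1e3, 1e5):
        raise ValueError(f"factor must be 1000 or 100000, got {factor!r}")
    return mean * factor, sd * factor


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one arm: mean, SD and sample size.

    n may be fractional for control arms shared between clinical groups.
    Positive mean and SD are required because the log-CV measures take
    logarithms of both.
    """
    mean: float
    sd: float
    n: float

    def __post_init__(self):
        if not (self.n >= 2):
            raise ValueError(f"n must be >= 2, got {self.n} (bias term 1/(2(n-1)) undefined)")
        if not (self.sd > 0):
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if not (self.mean > 0):
            raise ValueError(f"mean must be > 0 for log-CV measures, got {self.mean}")


@dataclass(frozen=True)
class StudyRecord:
    """One validated cohort x region x metabolite comparison."""
    study_id: str
    cohort_id: str
    region: str
    metabolite: str
    patient: GroupSummary
    control: GroupSummary
    medication_status: str = "mixed"
    acquisition: str = "standard"
    reference_scheme: str = "other"
    moderators: Mapping[str, float] = field(default_factory=dict)
    timepoint: int = 1
    n_clinical_groups: int = 1

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")
        if self.metabolite not in METABOLITES:
            raise ValueError(f"metabolite {self.metabolite!r} not in {METABOLITES}")
        if self.medication_status not in MEDICATION_STATUSES:
            raise ValueError(f"medication_status {self.medication_status!r} not in {MEDICATION_STATUSES}")
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(f"acquisition {self.acquisition!r} not in {ACQUISITIONS}")
        if self.reference_scheme not in REFERENCE_SCHEMES:
            raise ValueError(f"reference_scheme {self.reference_scheme!r} not in {REFERENCE_SCHEMES}")


@dataclass
class IngestResult:
    """Validated records plus a full account of everything not analysed."""
    records: list[StudyRecord]
    rejects: pd.DataFrame          # columns: row, study_id, reason
    summary: dict

    def write_reports(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)
        import json
        with open(out / "validation_summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _get(row, name, default=None):
    val = row.get(name, default)
    if val is None:
        return default
    if isinstance(val, float) and math.isnan(val):
        return default
    return val


def read_study_table(path: str | Path, delimiter: str | None = None,
                     control_n_mode: str = "fractional") -> IngestResult:
    """Read a CSV/TSV study-level table into validated :class:`StudyRecord` s.

    Every input row either becomes a record or appears in the rejects report
    with a reason; nothing is dropped silently.  Missing mandatory columns
    are a hard error.  Later timepoints of longitudinal studies are filtered
    (with reason ``"not first timepoint"``); de-duplication of overlapping
    samples across publications is a curation decision left to the table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    # first-timepoint filter needs the study minimum before row validation
    tp = pd.to_numeric(df.get("timepoint", pd.Series(["1"] * len(df))),
                       errors="coerce").fillna(1)
    first_tp = tp.groupby(df["study_id"]).transform("min")

    records: list[StudyRecord] = []
    rejects: list[dict] = []

    def reject(i, row, reason):
        rejects.append({"row": int(i), "study_id": _get(row, "study_id", ""),
                        "reason": reason})

    for i, raw in df.iterrows():
        row = raw.to_dict()
        if tp.iloc[i] > first_tp.iloc[i]:
            reject(i, row, "not first timepoint")
            continue
        nums = {}
        bad = None
        for col in ("n_patients", "mean_patients", "sd_patients",
                    "n_controls", "mean_controls", "sd_controls"):
            v = pd.to_numeric(row.get(col), errors="coerce")
            if v is None or (isinstance(v, float) and math.isnan(v)):
                bad = f"non-numeric {col}"
                break
            nums[col] = float(v)
        if bad:
            reject(i, row, bad)
            continue
        try:
            region = assign_region(row["region"])
        except (KeyError, ValueError) as exc:
            reject(i, row, f"unmapped region: {exc}")
            continue
        metabolite = str(row["metabolite"]).strip()
        if metabolite.lower() == "glx":
            metabolite = "Glx"
        acquisition = str(_get(row, "acquisition", "standard")).strip() or "standard"
        scale = _get(row, "scale_factor")
        if scale is not None:
            try:
                scale = float(scale)
                for arm in ("patients", "controls"):
                    m, s = rescale_metabolite(nums[f"mean_{arm}"], nums[f"sd_{arm}"],
                                              scale, acquisition)
                    nums[f"mean_{arm}"], nums[f"sd_{arm}"] = m, s
            except ValueError as exc:
                reject(i, row, f"invalid rescaling: {exc}")
                continue
        n_groups = int(float(_get(row, "n_clinical_groups", 1)))
        eff_nc = adjust_control_n(nums["n_controls"], n_groups, mode=control_n_mode)
        if eff_nc < 2:
            reject(i, row, "adjusted control n < 2 makes bias term undefined")
            continue
        if nums["n_patients"] < 2:
            reject(i, row, "n < 2 makes bias term undefined")
            continue
        for arm in ("patients", "controls"):
            if not nums[f"sd_{arm}"] > 0:
                bad = "non-positive SD"
            elif not nums[f"mean_{arm}"] > 0:
                bad = "non-positive mean"
        if bad:
            reject(i, row, bad)
            continue
        mods = {}
        for name in MODERATORS:
            v = pd.to_numeric(_get(row, name), errors="coerce")
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                mods[name] = float(v)
        try:
            rec = StudyRecord(
                study_id=str(row["study_id"]).strip(),
                cohort_id=str(_get(row, "cohort_id", row["study_id"])).strip(),
                region=region,
                metabolite=metabolite,
                patient=GroupSummary(nums["mean_patients"], nums["sd_patients"],
                                     nums["n_patients"]),
                control=GroupSummary(nums["mean_controls"], nums["sd_controls"],
                                     eff_nc),
                medication_status=str(_get(row, "medication_status", "mixed")).strip(),
                acquisition=acquisition,
                reference_scheme=str(_get(row, "reference_scheme", "other")).strip(),
                moderators=mods,
                timepoint=int(tp.iloc[i]),
                n_clinical_groups=n_groups,
            )
        except ValueError as exc:
            reject(i, row, str(exc))
            continue
        records.append(rec)

    rejects_df = pd.DataFrame(rejects, columns=["row", "study_id", "reason"])
    summary = {
        "n_rows": int(len(df)),
        "n_records": len(records),
        "n_rejected": len(rejects_df),
        "control_n_mode": control_n_mode,
        "region_synonyms_version": REGION_SYNONYMS_VERSION,
        "reject_reasons": rejects_df["reason"].value_counts().to_dict() if len(rejects_df) else {},
    }
    return IngestResult(records=records, rejects=rejects_df, summary=summary)


def records_to_frame(records: Iterable[StudyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "study_id": r.study_id, "cohort_id": r.cohort_id,
            "timepoint": r.timepoint, "region": r.region,
            "metabolite": r.metabolite,
            "medication_status": r.medication_status,
            "n_patients": r.patient.n, "mean_patients": r.patient.mean,
            "sd_patients": r.patient.sd,
            "n_controls": r.control.n, "mean_controls": r.control.mean,
            "sd_controls": r.control.sd,
            "n_clinical_groups": r.n_clinical_groups,
            "acquisition": r.acquisition,
            "reference_scheme": r.reference_scheme,
        }
        for name in MODERATORS:
            if name in r.moderators:
                row[name] = r.moderators[name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_study_table(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Serialise records back to CSV/TSV (delimiter from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False,
                                     float_format="%.10g")
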