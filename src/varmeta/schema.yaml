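# Column dictionary for varmeta study-level summary tables (schema v1).
#
# One row per study cohort x brain region x metabolite.  UTF-8, decimal
# point, CSV or TSV.  Unknown extra columns are preserved but ignored.
schema_version: 1
columns:
  study_id:
    required: true
    type: str
    description: Publication identifier (e.g. first author + year).
  cohort_id:
    required: false
    type: str
    default: same as study_id
    description: >
      Distinguishes multiple clinical groups reported by one study; each
      cohort is treated as an independent data set.
  timepoint:
    required: false
    type: int
    default: 1
    description: >
      Longitudinal studies contribute their first timepoint only; rows with
      timepoint greater than the study minimum are filtered out (reported,
      never silently dropped).
  region:
    required: true
    type: str
    description: >
      One of the six canonical brain regions (MFC, DLPFC,
      frontal_white_matter, thalamus, temporal_lobe, basal_ganglia) or a
      free-text voxel label resolvable through the shipped synonym table.
  metabolite:
    required: true
    type: str
    values: [glutamate, glutamine, Glx]
  medication_status:
    required: false
    type: str
    values: [antipsychotic_naive, medicated, mixed]
    default: mixed
  n_patients: {required: true, type: float, description: patient arm sample size}
  mean_patients: {required: true, type: float, description: patient arm mean metabolite level}
  sd_patients: {required: true, type: float, description: patient arm standard deviation}
  n_controls:
    required: true
    type: float
    description: >
      Control arm sample size as published; divided by n_clinical_groups when
      several cohorts share one control group.
  mean_controls: {required: true, type: float}
  sd_controls: {required: true, type: float}
  n_clinical_groups:
    required: false
    type: int
    default: 1
    description: Number of clinical groups sharing the control arm.
  acquisition:
    required: false
    type: str
    values: [standard, j_edited, epsi]
    default: standard
  scale_factor:
    required: false
    type: float
    values: [1000, 100000]
    description: >
      Rescaling factor applied to means and SDs of j_edited / epsi
      acquisitions so values are numerically comparable across studies;
      scale-invariant effect sizes are unaffected.
  reference_scheme:
    required: false
    type: str
    values: [cr_scaled, csf_corrected, other]
    default: other
moderators:
  # All optional; rows lacking a moderator drop out of that meta-regression
  # only, never of the pooled analysis.
  mean_age: {type: float, units: years, description: combined patient+control mean age}
  age_sd: {type: float, units: years}
  prop_male: {type: float, units: proportion in [0, 1]}
  panss_total: {type: float, units: PANSS total score}
  panss_total_sd: {type: float}
  cpz: {type: float, units: chlorpromazine-equivalent mg/day}
  snr_ratio: {type: float, description: patient/control spectral signal-to-noise ratio}
  fwhm_ratio: {type: float, description: patient/control linewidth (FWHM) ratio}
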