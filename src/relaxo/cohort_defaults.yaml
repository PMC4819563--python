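# Default synthetic-cohort parameters: group-level summary statistics of an
# extremely-preterm (EP) vs term-born adolescent cohort, stratified by sex.
#
# Strata sizes follow the study design the pipeline emulates: 43 EP subjects
# (16 male, 27 female) and 20 term-born controls (10 male, 10 female).
# White-matter volume, effective single-component WM T2, and WM myelin water
# fraction (MWF) means/SDs are the published group summaries; the per-stratum
# splits are chosen so the marginal group / sex means reproduce those
# summaries under the stratum sizes.  GM and CSF volumes are realistic
# adolescent values consistent with the reported direction of group
# differences (smaller in EP, larger in males); they are not acceptance
# quantities.
#
# Units: volumes in liters, T2 in ms, fractions dimensionless.
acquisition:
  echo_times_ms: [13, 16, 20, 25, 30, 40, 50, 85, 100, 150]
  voxel_dims_mm: [2.5, 2.5, 3.0]
  # Desk-scale factor applied to each voxel dimension: fewer, larger voxels
  # represent the same liters, keeping whole-cohort runs fast.  1.0 restores
  # the native acquisition grid (needs grid_shape ~ [96, 96, 56]).
  voxel_scale: 2.0
  grid_shape: [26, 26, 16]
  snr_first_echo: 150.0  # mean WM first-echo signal / noise SD
  s0: 1000.0             # proton-density amplitude, arbitrary units

basis_t2_ms: [20, 80, 2000]  # myelin water / tissue water / free water

# Fixed compartment fractions of non-WM tissues (myelin, tissue, free water).
gm_fractions: [0.06, 0.86, 0.08]
csf_fractions: [0.0, 0.0, 1.0]

strata:
  preterm_male:
    n_subjects: 16
    wm_volume_l:  {mean: 0.38, sd: 0.04}
    gm_volume_l:  {mean: 0.60, sd: 0.05}
    csf_volume_l: {mean: 0.19, sd: 0.03}
    wm_mwf:       {mean: 0.2563, sd: 0.06}
    wm_t2_ms:     {mean: 68.7, sd: 3.4}
  preterm_female:
    n_subjects: 27
    wm_volume_l:  {mean: 0.35, sd: 0.04}
    gm_volume_l:  {mean: 0.56, sd: 0.05}
    csf_volume_l: {mean: 0.18, sd: 0.03}
    wm_mwf:       {mean: 0.2463, sd: 0.06}
    wm_t2_ms:     {mean: 69.5, sd: 3.8}
  term_male:
    n_subjects: 10
    wm_volume_l:  {mean: 0.43, sd: 0.04}
    gm_volume_l:  {mean: 0.65, sd: 0.05}
    csf_volume_l: {mean: 0.22, sd: 0.03}
    wm_mwf:       {mean: 0.26, sd: 0.05}
    wm_t2_ms:     {mean: 67.8, sd: 2.8}
  term_female:
    n_subjects: 10
    wm_volume_l:  {mean: 0.37, sd: 0.03}
    gm_volume_l:  {mean: 0.59, sd: 0.05}
    csf_volume_l: {mean: 0.21, sd: 0.03}
    wm_mwf:       {mean: 0.26, sd: 0.05}
    wm_t2_ms:     {mean: 66.8, sd: 2.4}
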