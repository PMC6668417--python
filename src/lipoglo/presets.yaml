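# Genotype presets for the synthetic assay generators.
#
# These are qualitative encodings of the lipoprotein phenotypes of the four
# larval-zebrafish genotypes at ~4 dpf, chosen by the package authors as
# declared fixtures (the published work reports shapes, not numeric class
# weights).  Every field may be overridden at call time.
#
# class_weights: fraction of total ApoB-NanoLuc gel signal per mobility
#   subclass (ZM = zero mobility, then VLDL/IDL/LDL by increasing mobility).
# bands: Gaussian band components in ladder-unit (LU) space.  Each band has a
#   subclass, a centre (LU), a width sigma_lu, and a within-preset weight.
#   Weights across bands sum to 1 and, summed per subclass, reproduce
#   class_weights.  The mtp mutant's LDL is bimodal (two sub-bands).
# region_fractions: fraction of whole-larva chemiluminescent signal in the
#   viscera / trunk / head regions of interest.
# gradient_peak_fraction: density-gradient fraction (1 = densest, eluted
#   first; 10 = most buoyant) at which the reporter signal peaks.  Buoyant
#   VLDL-rich profiles (apoc2_mut) peak late; dense LDL-shifted profiles
#   (mtp_mut, pla2g12b_mut) peak early.

presets:
  WT:
    class_weights: {ZM: 0.15, VLDL: 0.25, IDL: 0.40, LDL: 0.20}
    bands:
      - {subclass: ZM,   center_lu: 0.15, sigma_lu: 0.05, weight: 0.15}
      - {subclass: VLDL, center_lu: 0.65, sigma_lu: 0.10, weight: 0.25}
      - {subclass: IDL,  center_lu: 1.35, sigma_lu: 0.10, weight: 0.40}
      - {subclass: LDL,  center_lu: 2.05, sigma_lu: 0.10, weight: 0.20}
    region_fractions: {viscera: 0.60, trunk: 0.25, head: 0.15}
    gradient_peak_fraction: 6.0
    gradient_peak_width: 1.5
  mtp_mut:
    # Defective lipoprotein synthesis: low counts, LDL-shifted with a
    # bimodal small-particle peak, viscera-enriched localization.
    class_weights: {ZM: 0.10, VLDL: 0.05, IDL: 0.15, LDL: 0.70}
    bands:
      - {subclass: ZM,   center_lu: 0.15, sigma_lu: 0.05, weight: 0.10}
      - {subclass: VLDL, center_lu: 0.65, sigma_lu: 0.10, weight: 0.05}
      - {subclass: IDL,  center_lu: 1.35, sigma_lu: 0.10, weight: 0.15}
      - {subclass: LDL,  center_lu: 1.90, sigma_lu: 0.07, weight: 0.35}
      - {subclass: LDL,  center_lu: 2.20, sigma_lu: 0.07, weight: 0.35}
    region_fractions: {viscera: 0.80, trunk: 0.12, head: 0.08}
    gradient_peak_fraction: 4.0
    gradient_peak_width: 1.5
  apoc2_mut:
    # Defective lipolysis: persistent VLDL-dominant profile, buoyant
    # gradient peak, near-WT regional distribution.
    class_weights: {ZM: 0.15, VLDL: 0.70, IDL: 0.10, LDL: 0.05}
    bands:
      - {subclass: ZM,   center_lu: 0.15, sigma_lu: 0.05, weight: 0.15}
      - {subclass: VLDL, center_lu: 0.65, sigma_lu: 0.10, weight: 0.70}
      - {subclass: IDL,  center_lu: 1.35, sigma_lu: 0.10, weight: 0.10}
      - {subclass: LDL,  center_lu: 2.05, sigma_lu: 0.10, weight: 0.05}
    region_fractions: {viscera: 0.55, trunk: 0.28, head: 0.17}
    gradient_peak_fraction: 9.0
    gradient_peak_width: 1.2
  pla2g12b_mut:
    # Secretion defect biased toward abnormally small LDL-like particles.
    class_weights: {ZM: 0.10, VLDL: 0.10, IDL: 0.20, LDL: 0.60}
    bands:
      - {subclass: ZM,   center_lu: 0.15, sigma_lu: 0.05, weight: 0.10}
      - {subclass: VLDL, center_lu: 0.65, sigma_lu: 0.10, weight: 0.10}
      - {subclass: IDL,  center_lu: 1.35, sigma_lu: 0.10, weight: 0.20}
      - {subclass: LDL,  center_lu: 2.10, sigma_lu: 0.09, weight: 0.60}
    region_fractions: {viscera: 0.75, trunk: 0.15, head: 0.10}
    gradient_peak_fraction: 4.0
    gradient_peak_width: 1.5

# Published reference summaries of negative-staining electron-microscopy
# particle diameters (nm) for wild-type density-gradient fractions; used as
# generator defaults for synthetic particle populations.
em_reference:
  wt_fraction4:  {mean_nm: 24.7, sd_nm: 5.6, n: 170}
  wt_fraction7:  {mean_nm: 29.0, sd_nm: 4.1, n: 170}
  wt_fraction10: {mean_nm: 34.9, sd_nm: 4.7, n: 170}
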