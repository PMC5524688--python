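# 2-naphthol photoacid family: kinetic parameters of the spherically-symmetric
# diffusion fits, free in pH 7 buffer and bound to insulin amyloid fibrils,
# plus steady-state RO-*/ROH* band ratios and registry metadata.
# Units: k_PT 1/ns; k_a Å/ns; R_D Å; D cm^2/s; a Å; wavelengths nm.
# k_PT_fast is the fast component of the 3-exponential IRF reconvolution,
# which corrects the IRF-limited direct estimate for the fastest dissociators.
medium:
  relative_permittivity: 80.1   # water at 20 degC
  temperature_K: 293.15

photoacids:
  2N:
    anion_charge_Z1: 1
    pKa: 9.3
    pKa_star: 2.8
    collection_wavelength_nm: 350
    ro_band_center_nm: 420
    band_width_nm: 20.0
    ratio_free: 0.74
    ratio_bound: 0.70
    bathochromic_shift_bound_nm: 5.0
    buffer:  {k_PT: 0.2, k_a: 0.2, d: 3.0, R_D: 7.0,  D: 9.0e-5, a: 4.0}
    fibrils: {k_PT: 0.4, k_a: 1.5, d: 1.2, R_D: 10.0, D: 5.0e-5, a: 4.0}
  2N6S:
    anion_charge_Z1: 2
    pKa: 9.2
    pKa_star: 1.7
    collection_wavelength_nm: 355
    ro_band_center_nm: 420
    band_width_nm: 20.0
    ratio_free: 16.6
    ratio_bound: 6.5
    bathochromic_shift_bound_nm: 0.0
    buffer:  {k_PT: 1.0, k_a: 0.8, d: 3.0, R_D: 14.0, D: 9.0e-5, a: 4.0}
    fibrils: {k_PT: 0.9, k_a: 0.7, d: 1.9, R_D: 19.0, D: 2.5e-5, a: 4.0}
  2N8S:
    anion_charge_Z1: 2
    pKa: 9.2
    pKa_star: 1.0
    collection_wavelength_nm: 355
    ro_band_center_nm: 420
    band_width_nm: 20.0
    ratio_free: 18.2
    ratio_bound: 4.9
    bathochromic_shift_bound_nm: 0.0
    k_PT_fast: 3.9
    buffer:  {k_PT: 1.6, k_a: 1.5, d: 3.0, R_D: 14.0, D: 9.0e-5, a: 4.0}
    fibrils: {k_PT: 0.9, k_a: 1.4, d: 2.1, R_D: 16.0, D: 2.6e-5, a: 4.0}
  2N6,8S:
    anion_charge_Z1: 3
    pKa: 9.2
    pKa_star: 0.4
    collection_wavelength_nm: 370
    ro_band_center_nm: 420
    band_width_nm: 20.0
    ratio_free: 48.5
    ratio_bound: 6.4
    bathochromic_shift_bound_nm: 0.0
    k_PT_fast: 10.6
    buffer:  {k_PT: 1.8, k_a: 1.3, d: 3.0, R_D: 21.0, D: 9.0e-5, a: 4.0}
    fibrils: {k_PT: 0.6, k_a: 1.2, d: 2.9, R_D: 22.0, D: 2.0e-5, a: 4.0}
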