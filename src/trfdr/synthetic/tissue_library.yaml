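# Pure-tissue optical library used by the synthetic generator.
# These values are generator parameters chosen to give plausible contrast
# between tissue types; they are NOT measured ground truth.
version: 1
emission_bands:   # Gaussian emission shape per fluorophore over 380-570 nm
  collagen: {peak_nm: 400.0, width_nm: 32.0}
  nadh:     {peak_nm: 460.0, width_nm: 42.0}
  fad:      {peak_nm: 525.0, width_nm: 38.0}
tissues:
  tumor:
    yields:       {collagen: 0.30, nadh: 1.00, fad: 0.45}
    lifetimes_ns: {collagen: 4.20, nadh: 0.55, fad: 2.00}
    absorption:   {oxy: 0.060, deoxy: 0.040, offset: 0.012}   # basis coefficients
    scattering:   {amplitude: 2.4, power: 1.4}                # a * (lambda/500)^-b
  fibroglandular:
    yields:       {collagen: 1.00, nadh: 0.40, fad: 0.30}
    lifetimes_ns: {collagen: 5.30, nadh: 1.20, fad: 2.70}
    absorption:   {oxy: 0.030, deoxy: 0.015, offset: 0.008}
    scattering:   {amplitude: 1.8, power: 1.1}
  adipose:
    yields:       {collagen: 0.15, nadh: 0.25, fad: 0.50}
    lifetimes_ns: {collagen: 4.80, nadh: 1.15, fad: 2.40}
    absorption:   {oxy: 0.008, deoxy: 0.005, offset: 0.004}
    scattering:   {amplitude: 1.1, power: 0.6}
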