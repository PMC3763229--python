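# nirspeech-extinction v1
# units: 1/(mM*cm), decadic
# source: compiled adult hemoglobin absorption spectra (Gratzer/Kollias tabulation), interpolated to the instrument wavelengths
wavelength_nm	o2hb	hhb
763	0.590	1.490
860	1.080	0.780
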