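wavelength_nm,n,k
500,2.75,4.46
550,3.18,4.41
600,3.48,4.36
650,3.58,4.37
700,3.64,4.44
750,3.54,4.57
800,3.43,4.70
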