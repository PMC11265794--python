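wavelength_nm,n,k
500,0.97,1.87
520,0.62,2.08
540,0.43,2.35
560,0.35,2.60
580,0.29,2.84
600,0.25,3.07
620,0.21,3.29
640,0.18,3.52
660,0.15,3.74
680,0.14,3.95
700,0.13,4.17
720,0.13,4.38
740,0.14,4.58
760,0.14,4.78
780,0.15,4.97
800,0.16,5.16
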