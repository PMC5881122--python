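# Combined human lens + macular pigment optical density, approximate
# digitisation of standard tabulated human values (open-pupil lens
# density plus foveal macular pigment, peak density ~0.5 near 460 nm).
# Columns: wavelength (nm), optical density (log10 units).
wavelength,density
400,1.90
410,1.45
420,1.15
430,0.97
440,0.88
450,0.83
460,0.80
470,0.68
480,0.52
490,0.38
500,0.26
510,0.17
520,0.11
530,0.08
540,0.062
550,0.052
560,0.045
570,0.039
580,0.034
590,0.030
600,0.026
610,0.023
620,0.020
630,0.017
640,0.015
650,0.012
660,0.010
670,0.008
680,0.005
690,0.003
700,0.000
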