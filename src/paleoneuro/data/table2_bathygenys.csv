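specimen_id,E_ml,S_cm2,nc_cm2,nc_over_S
443D,11.362,28.5,8.22,0.288421
443F,10.98,31.5,8.64,0.274286
443H,11.386,34,8.3,0.244118
443I,11.914,34.5,8.32,0.241159
443J,13.557,28.8,7.62,0.264583
443K,13.981,30.8,8.24,0.267532
443L,10.386,28.3,6.96,0.245936
443X,11.422,25.8,7.1,0.275194
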