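wavelength_nm,k
1300,1.2311e-05
1350,3.2229e-05
1400,1.2812e-04
1425,2.2680e-04
1450,3.4039e-04
1475,2.8170e-04
1500,2.4470e-04
1550,1.2581e-04
1600,8.2761e-05
1650,6.3025e-05
1700,6.2230e-05
1750,9.0519e-05
1800,1.3321e-04
1825,1.7427e-04
1850,2.5027e-04
1875,4.0100e-04
1900,9.8278e-04
1925,1.6085e-03
1950,1.8621e-03
2000,1.0982e-03
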