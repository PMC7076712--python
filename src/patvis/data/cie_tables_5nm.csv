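# CIE colour tables for tristimulus computation (380-780 nm, 5 nm step).
# xbar/ybar/zbar: CIE 1931 2-degree colour-matching functions evaluated from
#   the multi-lobe Gaussian analytic fit of Wyman, Sloan & Shirley,
#   "Simple analytic approximations to the CIE XYZ color matching functions",
#   Journal of Computer Graphics Techniques 2(2), 2013.
# S: daylight-like relative spectral power (Planckian radiator at 6504 K,
#   normalised to 100 at 560 nm).
# Regenerate with patvis.colorimetry.make_cie_tables().
wavelength_nm,xbar,ybar,zbar,S
380,0.0001987095,0.00024854046,0.006746243,105.24875
385,0.00063515116,0.00037958927,0.011934978,106.35726
390,0.0018413677,0.00057318488,0.020564848,107.36105
395,0.0048417328,0.00085573537,0.035075823,108.26262
400,0.011546588,0.0012631304,0.060794991,109.06463
405,0.024974471,0.0018434055,0.10957313,109.76991
410,0.048992118,0.0026598522,0.20411363,110.38137
415,0.087164605,0.003794531,0.37668608,110.90205
420,0.14064769,0.0053520809,0.65220019,111.33505
425,0.20582248,0.0074636488,1.0152473,111.68352
430,0.2731485,0.010290672,1.3862369,111.95063
435,0.32870312,0.014028149,1.6444008,112.1396
440,0.35859576,0.018906958,1.7341988,112.25362
445,0.35849233,0.025194715,1.7764162,112.29589
450,0.34371675,0.033194791,1.7815809,112.26956
455,0.31719319,0.043243586,1.7469871,112.17778
460,0.28104655,0.05570773,1.6715433,112.02362
465,0.23810018,0.070986549,1.518934,111.81013
470,0.19154448,0.089532177,1.2951684,111.54029
475,0.14464986,0.11190913,1.0449141,111.21701
480,0.10055437,0.13891934,0.81027531,110.84313
485,0.062111792,0.1717988,0.61576068,110.42144
490,0.031762745,0.21242353,0.46637669,109.95463
495,0.011402134,0.26334354,0.35505567,109.44532
500,0.0022533296,0.32735772,0.27144376,108.89604
505,0.0043348587,0.40639756,0.20705612,108.30927
510,0.01654377,0.49983757,0.15647916,107.68736
515,0.038563686,0.6029321,0.11656798,107.03262
520,0.07004303,0.70649772,0.085353983,106.34726
525,0.11061554,0.79869229,0.061350884,105.63339
530,0.1599135,0.86864005,0.043265981,104.89307
535,0.21753529,0.91675412,0.02993125,104.12826
540,0.28297244,0.95393878,0.020311085,103.34084
545,0.35550862,0.9798778,0.013519651,102.53261
550,0.43410955,0.99446404,0.0088271517,101.70531
555,0.51732716,0.99803862,0.0056532495,100.86058
560,0.60324077,0.99128193,0.0035513881,100
565,0.68945432,0.97509469,0.0021883688,99.12508
570,0.77315988,0.95039783,0.0013227121,98.237254
575,0.85126816,0.91608581,0.00078421024,97.33789
580,0.92059604,0.87244574,0.00045606014,96.428288
585,0.97809214,0.82086846,0.00026015617,95.509689
590,1.0210755,0.76289601,0.00014556888,94.583266
595,1.0474592,0.70018011,7.9896059e-05,93.650136
600,1.0559257,0.63443207,4.3013481e-05,92.711358
605,1.0412225,0.56736327,2.2714659e-05,91.767935
610,1.0003456,0.50061884,1.1766038e-05,90.820815
615,0.93638797,0.43571016,5.9782862e-06,89.870896
620,0.85400855,0.37395307,2.9795148e-06,88.919026
625,0.75887452,0.31641876,1.4565883e-06,87.966006
630,0.65702126,0.26390244,6.9847437e-07,87.01259
635,0.55423091,0.21691256,3.285387e-07,86.059489
640,0.45551639,0.17568031,1.5158109e-07,85.107372
645,0.36477012,0.14018691,6.8600281e-08,84.156868
650,0.28460106,0.1102039,3.0452937e-08,83.208567
655,0.21634944,0.085341377,1.3260346e-08,82.263022
660,0.16024225,0.065098474,5.6637355e-09,81.320751
665,0.11563794,0.048911585,2.3728674e-09,80.38224
670,0.081306569,0.036196654,9.7513867e-10,79.447942
675,0.055699713,0.026383388,3.9308067e-10,78.518278
680,0.037177681,0.018940465,1.5542448e-10,77.593641
685,0.024177626,0.013391934,6.0280874e-11,76.674398
690,0.015319586,0.00932577,2.2933063e-11,75.760887
695,0.0094576319,0.0063960555,8.5578961e-12,74.853422
700,0.0056887888,0.0043204008,3.1325236e-12,73.952294
705,0.0033339512,0.0028742126,1.1247192e-12,73.057769
710,0.0019037095,0.0018831978,3.9611041e-13,72.170094
715,0.0010591175,0.0012152193,1.3683929e-13,71.289494
720,0.00057410271,0.00077231536,4.6369006e-14,70.416175
725,0.00030320551,0.00048341013,1.5412289e-14,69.550325
730,0.00015602227,0.000298001,5.0249175e-15,68.692114
735,7.8223656e-05,0.00018092581,1.6069898e-15,67.841696
740,3.8211285e-05,0.00010818426,5.041035e-16,66.999209
745,1.8186419e-05,6.3710109e-05,1.5511318e-16,66.164776
750,8.4334402e-06,3.6951606e-05,4.6816626e-17,65.338507
755,3.8103455e-06,2.1107606e-05,1.3860341e-17,64.520497
760,1.6773588e-06,1.1874773e-05,4.0250393e-18,63.71083
765,7.1943172e-07,6.5794912e-06,1.1465388e-18,62.909579
770,3.0064585e-07,3.5903765e-06,3.2035372e-19,62.116803
775,1.2241168e-07,1.9296046e-06,8.7799735e-20,61.332554
780,4.856155e-08,1.0213565e-06,2.3603643e-20,60.556872
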