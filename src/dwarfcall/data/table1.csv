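accession_id,genotype,height_cm_mean,height_cm_sd
8R241,Dw1Dw2dw3-c,46.0,3.5
8R257,Dw1Dw2Dw3,141.0,14.7
8R258,Dw1Dw2dw3-c,129.3,6.0
8R270,Dw1Dw2dw3-ref,154.3,17.9
8R272,Dw1Dw2dw3-ref,150.3,6.0
8R274,Dw1Dw2Dw3,195.3,15.5
8R275,Dw1Dw2dw3-ref,132.3,2.5
8R277,Dw1Dw2Dw3,156.7,9.8
8R281,Dw1Dw2Dw3,135.0,5.0
8R288,Dw1Dw2Dw3,174.7,12.7
8R299,dw1Dw2Dw3,133.7,8.1
8R315,Dw1dw2Dw3,160.3,8.4
8R336,Dw1Dw2dw3-ref,134.0,7.2
8R337,dw1Dw2dw3-ref,71.7,4.7
8R351,Dw1dw2dw3-ref,128.3,2.3
8R360,dw1Dw2dw3-ref,79.7,4.9
8R361,dw1Dw2dw3-ref,98.0,10.6
8R366,Dw1Dw2Dw3,121.0,24.1
8R396,Dw1Dw2Dw3,183.7,9.3
8R402,Dw1Dw2dw3-b,124.7,5.5
8R414,Dw1Dw2Dw3,176.0,12.8
8R415,Dw1Dw2Dw3,150.7,16.3
8R417,Dw1Dw2dw3-c,131.0,5.3
8R428,Dw1Dw2dw3-c,169.7,13.1
8R431,Dw1Dw2Dw3,100.3,10.3
8R462,Dw1Dw2Dw3,170.0,21.4
8R463,Dw1Dw2Dw3,170.0,17.4
8R617,Dw1Dw2dw3-ref,188.7,8.1
8R633,Dw1Dw2dw3-ref,101.0,11.5
8R634,Dw1Dw2dw3-ref,93.7,5.7
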