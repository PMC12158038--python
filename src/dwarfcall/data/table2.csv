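cultivar_id,origin,genotype,height_cm_mean,height_cm_sd
8R252,China,Dw1Dw2Dw3,265.0,11.8
8R387,Mexico,dw1dw2dw3-ref,66.3,4.2
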