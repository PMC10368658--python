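lambda_lo_nm,lambda_hi_nm,nm_per_pixel
445,480,1.67
480,510,2.00
510,560,2.50
560,602,3.33
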