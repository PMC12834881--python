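dose_mgy,algorithm,level,dprime_low_contrast,dprime_high_contrast
3.0,AiCE,1,2.4,11.3
3.0,AiCE,2,3.0,14.2
3.0,AiCE,3,3.4,16.2
3.0,PIQE,1,2.7,12.0
3.0,PIQE,2,4.5,20.8
3.0,PIQE,3,6.0,27.6
5.9,AiCE,1,2.9,13.1
5.9,AiCE,2,3.5,16.4
5.9,AiCE,3,4.0,18.6
5.9,PIQE,1,3.1,13.6
5.9,PIQE,2,5.0,22.9
5.9,PIQE,3,6.8,30.9
12.7,AiCE,1,3.8,16.4
12.7,AiCE,2,4.2,18.7
12.7,AiCE,3,4.4,19.7
12.7,PIQE,1,4.1,17.0
12.7,PIQE,2,6.5,26.9
12.7,PIQE,3,8.2,35.3
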