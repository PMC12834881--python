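dose_mgy,algorithm,level,f50_solid_water,f50_iodine
3.0,AiCE,1,0.25,0.33
3.0,AiCE,2,0.26,0.34
3.0,AiCE,3,0.26,0.35
3.0,PIQE,1,0.30,0.41
3.0,PIQE,2,0.29,0.41
3.0,PIQE,3,0.29,0.37
5.9,AiCE,1,0.28,0.40
5.9,AiCE,2,0.29,0.44
5.9,AiCE,3,0.29,0.46
5.9,PIQE,1,0.35,0.49
5.9,PIQE,2,0.34,0.48
5.9,PIQE,3,0.34,0.47
12.7,AiCE,1,0.30,0.41
12.7,AiCE,2,0.31,0.44
12.7,AiCE,3,0.32,0.46
12.7,PIQE,1,0.38,0.50
12.7,PIQE,2,0.38,0.49
12.7,PIQE,3,0.37,0.48
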