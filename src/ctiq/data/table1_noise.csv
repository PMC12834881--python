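dose_mgy,algorithm,level,nps1d_peak,noise_magnitude,f_av
3.0,AiCE,1,908.7,17.8,0.20
3.0,AiCE,2,671.2,14.9,0.19
3.0,AiCE,3,578.9,13.5,0.19
3.0,PIQE,1,446.2,17.9,0.28
3.0,PIQE,2,278.0,10.1,0.20
3.0,PIQE,3,266.1,7.8,0.16
5.9,AiCE,1,596.9,16.1,0.22
5.9,AiCE,2,449.8,13.5,0.22
5.9,AiCE,3,393.0,12.3,0.21
5.9,PIQE,1,271.2,18.2,0.35
5.9,PIQE,2,163.0,10.0,0.26
5.9,PIQE,3,139.0,7.0,0.20
12.7,AiCE,1,342.1,12.5,0.23
12.7,AiCE,2,296.9,11.7,0.23
12.7,AiCE,3,277.6,11.3,0.23
12.7,PIQE,1,161.7,16.0,0.40
12.7,PIQE,2,94.5,8.8,0.30
12.7,PIQE,3,80.4,6.2,0.24
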