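dataset,optimum,default,maximum
cline-ch,0.4280,0.4202,0.4369
HEK-HMEC-MULTI,0.4723,0.4830,0.4966
HEK-orig-MULTI,0.4911,0.4873,0.5054
hm-12k,0.9281,0.9506,0.9850
hm-6k,0.9737,0.9896,0.9972
HMEC-rep-MULTI,0.6010,0.5964,0.6020
J293t-dm,0.2052,0.1999,0.2525
mkidney-ch,0.6125,0.6080,0.6183
nuc-MULTI,0.4600,0.4430,0.4704
pbmc-1A-dm,0.5454,0.5441,0.5693
pbmc-1B-dm,0.4375,0.4145,0.4818
pbmc-1C-dm,0.5953,0.5744,0.6082
pbmc-2ctrl-dm,0.6980,0.6749,0.7088
pbmc-2stim-dm,0.7003,0.6763,0.7124
pbmc-ch,0.6405,0.6472,0.6520
pdx-MULTI,0.4457,0.4268,0.4477
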