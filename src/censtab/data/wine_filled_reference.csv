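year,CSI,CSII,TMI
1995,57.82,70.01,84.04
2000,42.04,69.54,64.02
2002,50.00,53.73,56.01
2003,27.98,50.53,56.56
2005,18.86,44.13,35.80
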