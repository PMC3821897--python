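year,CSI,CSII,TMI
1995,53.37,78.11,80.42
2000,44.23,64.73,66.65
2002,40.23,58.88,60.63
2003,34.02,49.79,51.26
2005,24.88,36.41,37.49
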