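year,CSI,CSII,TMI
1995,,70.01,
2000,,69.54,
2002,50.00,,
2003,27.98,,56.56
2005,18.86,,35.80
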