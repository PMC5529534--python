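year,prevalence
2011,63.5
2012,56.1
2013,60.3
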