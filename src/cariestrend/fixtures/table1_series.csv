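year,prevalence
1988,81.2
1989,74.2
1990,73.4
1991,83.0
1992,76.2
1993,74.2
1994,82.2
1995,66.3
1996,68.1
1997,79.5
1998,71.1
1999,56.4
2000,69.4
2001,55.1
2002,60.9
2003,56.8
2004,55.3
2005,66.4
2006,63.6
2007,62.0
2008,61.0
2009,60.1
2010,55.1
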