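no,progeny,parent1,parent2,parent1_label,parent2_label,progeny_label,aggregated_four_group,aggregated_six_group,pd_higher_assume_lower,pd_higher_exclude_unknown
1,M. 'Adams',M. baccata,unknown,D2,unknown,D2,yes,yes,yes,yes
2,M. 'Almey',M. baccata,M. pumila var. neidzwetzkyana,D2,D3,D2,yes,yes,yes,yes
3,M. 'Brandywine',,,,,,no,no,yes,no
4,M. 'Cardinal',,,,,,yes,no,yes,no
5,M. 'Dolgo',,,,,,yes,yes,yes,yes
6,M. 'Eleyi',,,,,,yes,yes,yes,no
7,M. 'Flame',M. pumila,unknown,D3,unknown,D3,yes,yes,yes,no
8,M. 'Golden Hornet',M. mandshurica,M. sieboldii,D3,untested,D3,yes,yes,yes,yes
9,M. 'Hillier',M. floribunda,M. prunifolia,D2,D1,D3,yes,no,yes,yes
10,M. 'Hopa',M. baccata,M. pumila var. neidzwetzkyana,D3,D3,D3,yes,yes,yes,yes
11,M. 'Klehm's Improved Bechtel',M. ioensis,unknown,D1,unknown,D2,yes,no,yes,yes
12,M. 'Lisa',M. ioensis,unknown,D1,unknown,D2,yes,no,yes,yes
13,M. 'Liset',,,,,,yes,yes,yes,no
14,M. 'Makamik',M. pumila var. neidzwetzkyana,unknown,D3,unknown,D3,yes,yes,yes,no
15,M. 'Prairie Rose',M. ioensis,unknown,D1,unknown,D2,yes,no,yes,yes
16,M. 'Professor Sprenger',M. mandshurica,M. sieboldii,D3,untested,D3,yes,yes,yes,yes
17,M. 'Profusion',,,,,,yes,yes,yes,no
18,M. 'Purple Prince',,,,,,yes,yes,yes,yes
19,M. 'Radiant',,,,,,yes,yes,yes,no
20,M. 'Red Jade',,,,,,yes,no,yes,no
21,M. 'Red Splendor',,,,,,yes,yes,yes,yes
22,M. 'Robinson',M. baccata,M. pumila,D2,D3,D3,yes,yes,no,no
23,M. 'Royalty',,,,,,yes,yes,yes,no
24,M. 'Rudolph',M. baccata,unknown,D2,unknown,D3,yes,no,yes,no
25,M. 'Sparkler',,,,,,yes,yes,yes,no
26,M. 'Spring Snow',,,,,,yes,yes,yes,yes
27,'Van Eseltine',,,,,,no,no,yes,yes
28,M. zumi 'Calocarpa',M. mandshurica,M. sieboldii,D3,untested,D3,yes,yes,yes,yes
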