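# Syntenic target chromosomes supporting each breeding hotspot.
# bd = Brachypodium distachyon, os = Oryza sativa, zm = Zea mays.
chromosome	hotspot_id	target_chromosomes
1A	qhotspot1	bd1,bd2,bd4,os1,os5,os11,os12,zm9
1B	qhotspot4	bd2,os5,os7
1B	qhotspot5	bd4,bd2
1B	qhotspot10	bd2,bd5,os5
2A	qhotspot15	bd5
2B	qhotspot26	bd5,os4,zm2
3B	qhotspot33	bd2,os1,os5,os6
3B	qhotspot35	bd2,bd3,os1,zm9
4B	qhotspot47	bd1,os3
4B	qhotspot52	bd1,os3,zm1
5A	qhotspot57	bd1,bd3,bd4,os3,os9,zm2,zm5
6A	qhotspot64	bd1,os6,os7
6A	qhotspot73	bd1,bd3,bd5,os2,os3,os8,os10,zm5
7A	qhotspot79	bd1,bd3,os8
7A	qhotspot81	bd1,os6
7A	qhotspot85	bd1,os6
7B	qhotspot92	bd3
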