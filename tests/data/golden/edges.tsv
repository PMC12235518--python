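gene1	gene2	confidence
G00	G01	999.0
G00	G02	999.0
G00	G03	999.0
G00	G04	999.0
G00	G05	999.0
G00	G07	999.0
G00	G10	999.0
G00	G11	999.0
G00	G16	999.0
G00	G18	999.0
G01	G03	999.0
G01	G04	999.0
G01	G05	999.0
G01	G06	999.0
G01	G09	999.0
G01	G10	999.0
G01	G13	999.0
G01	G14	999.0
G01	G15	999.0
G01	G16	999.0
G01	G17	999.0
G02	G06	999.0
G04	G07	999.0
G04	G11	999.0
G04	G12	999.0
G04	G19	999.0
G05	G08	999.0
G05	G09	999.0
G05	G17	999.0
G05	G19	999.0
G06	G08	999.0
G06	G15	999.0
G06	G18	999.0
G08	G12	999.0
G08	G13	999.0
G09	G14	999.0
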