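sample_id	sex	group	locality	year
Ca1	M	control_aurita	Biritiba Mirim/SP	2003
Ca2	F	control_aurita	PARNASO/RJ	2013
Ca3	M	control_aurita	PARNASO/RJ	2013
Ca4	M	control_aurita	PARNASO/RJ	2013
Ca5	M	control_aurita	Natividade/RJ	2015
Ca6	M	control_aurita	Natividade/RJ	2015
Cj1	M	control_jacchus	CPRJ Guapimirim/RJ	2009
Cj2	M	control_jacchus	Bosque da Barra/RJ	2011
Cj3	F	control_jacchus	Nogueira/RJ	2012
Cj4	F	control_jacchus	Recife/PE	2014
Cj5	M	control_jacchus	Recife/PE	2014
Cp1	F	control_penicillata	Correias/RJ	2012
Cp2	M	control_penicillata	Correias/RJ	2012
Cp3	F	control_penicillata	Juiz de Fora/MG	2012
Cp4	M	control_penicillata	Brasilia/DF	2014
Csp1	F	putative_hybrid	Biritiba Mirim/SP	2004
Csp2	M	putative_hybrid	Biritiba Mirim/SP	2004
Csp3	M	putative_hybrid	Guapimirim/RJ	2005
Csp4	M	putative_hybrid	Guapimirim/RJ	2005
Csp5	M	putative_hybrid	Guapimirim/RJ	2005
Csp6	M	putative_hybrid	PARNASO/RJ	2005
Csp7	M	putative_hybrid	PARNASO/RJ	2005
Csp8	M	putative_hybrid	PARNASO/RJ	2008
Csp9	M	putative_hybrid	Nogueira/RJ	2012
Csp10	M	putative_hybrid	Nogueira/RJ	2012
Csp11	F	putative_hybrid	Nogueira/RJ	2012
Csp12	M	putative_hybrid	Nogueira/RJ	2013
Csp13	M	putative_hybrid	Nogueira/RJ	2013
Csp14	M	putative_hybrid	Nogueira/RJ	2013
Csp15	M	putative_hybrid	Nogueira/RJ	2013
Csp16	M	putative_hybrid	Nogueira/RJ	2013
Csp17	M	putative_hybrid	Nogueira/RJ	2013
Csp18	F	putative_hybrid	Nogueira/RJ	2013
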