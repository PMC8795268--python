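sample_id	sry_allele	cox2_haplotype
Ca1	del	HCa
Ca2	del	HCa
Ca3	del	HCa
Ca4	del	HCa
Ca5	del	HCa
Ca6	del	HCa
Cj1	ins	HCj
Cj2	ins	HCj
Cj3	ins	HCj
Cj4	ins	HCj
Cj5	ins	HCj
Cp1	ins	HCp
Cp2	ins	HCp
Cp3	ins	HCp
Cp4	ins	HCp
Csp1	del	HCj
Csp2	del	HCj
Csp3	del	HCp2
Csp4	del	HCp2
Csp5	del	HCp2
Csp6	del	HCa
Csp7	del	HCp2
Csp8	del	HCa
Csp9	del	HCj
Csp10	del	HCj
Csp11	del	HCj
Csp12	del	HCp
Csp13	del	HCp
Csp14	del	HCp
Csp15	del	HCp
Csp16	del	HCp
Csp17	del	HCp
Csp18	del	HCp
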