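sample_id,size_bp
Ca1,196
Ca2,196
Ca3,196
Ca4,196
Ca5,196
Ca6,196
Cj1,205
Cj2,205
Cj3,205
Cj4,205
Cj5,205
Cp1,205
Cp2,205
Cp3,205
Cp4,205
Csp1,196
Csp2,196
Csp3,196
Csp4,196
Csp5,196
Csp6,196
Csp7,196
Csp8,196
Csp9,196
Csp10,196
Csp11,196
Csp12,196
Csp13,196
Csp14,196
Csp15,196
Csp16,196
Csp17,196
Csp18,196
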