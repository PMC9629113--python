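name,formula,Tm_printed_C,provenance,pH
CMP1,Ac-(POG)7-NH2,45,CD melting comparison series,7.4
CMP2,Ac-(GPO)7-NH2,55,CD melting comparison series,7.4
CMP3,Ac-G(POG)7-NH2,47,CD melting comparison series,7.4
CMP3S_N,Ac-Z(POG)7-NH2,,N-terminal sarcosine variant,7.4
CMP3A,H-G(POG)7-NH2,,free-amine N-terminus variant,7.4
CMP3S_C,Ac-G(POG)6POZ-NH2,,C-terminal sarcosine variant,7.4
CMP2O,Ac-(GPO)7-OH,,C-terminal carboxylate variant,7.4
CMP2E,Ac-(GPO)7-OCH3,,C-terminal ester variant,7.4
CMP4,Ac-(OGP)7-NH2,,OGP terminal-repeat form,7.4
POG8,Ac-(POG)8-NH2,56,length-extension series,7.4
GPO8,Ac-(GPO)8-NH2,64,length-extension series,7.4
CMP5,,,C-terminal extra-Pro variant (exact formula not reported),7.4
CMP6,,,C-terminal extra-Hyp variant (exact formula not reported),7.4
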