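metabolite,fragment_id,formula,n_backbone
pyruvate,mox_tbdms_m57,C6H12NO3Si,3
lactate,2tbdms_m57,C11H25O3Si2,3
alanine,2tbdms_m57,C11H26NO2Si2,3
pep,3tbdms_m57,C17H38O6PSi3,3
3pg,4tbdms_m57,C23H54O7PSi4,3
citrate,4tbdms_m57,C26H55O7Si4,6
isocitrate,4tbdms_m57,C26H55O7Si4,6
succinate,2tbdms_m57,C12H25O4Si2,4
fumarate,2tbdms_m57,C12H23O4Si2,4
malate,3tbdms_m57,C18H39O5Si3,4
glutamate,3tbdms_m57,C19H42NO4Si3,5
glutamine,3tbdms_m57,C19H43N2O3Si3,5
aspartate,3tbdms_m57,C18H40NO4Si3,4
serine,3tbdms_m57,C17H40NO3Si3,3
glycine,2tbdms_m57,C10H24NO2Si2,2
cystathionine,4tbdms_m57,C27H61N2O4SSi4,7
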