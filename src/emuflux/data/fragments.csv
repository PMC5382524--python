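# MS fragment database: name, abbreviation, formula, n_carbons, formula_no_backbone
# Underivatized (LC-MS / CE-MS) backbones and TBDMS-derivatized (GC-MS, M-57) ions.
name,abbreviation,formula,n_carbons,formula_no_backbone
glutamate,glu_12345,C5H9NO4,5,H9NO4
aspartate,asp_1234,C4H7NO4,4,H7NO4
alanine,ala_123,C3H7NO2,3,H7NO2
pyruvate,pyr_123,C3H4O3,3,H4O3
citrate,cit_123456,C6H8O7,6,H8O7
alpha-ketoglutarate,akg_12345,C5H6O5,5,H6O5
succinate,suc_1234,C4H6O4,4,H6O4
fumarate,fum_1234,C4H4O4,4,H4O4
glutamate_tbdms_m57,glu_m57,C19H40NO4Si2,5,C14H40NO4Si2
alanine_tbdms_m57,ala_m57,C14H32NO2Si2,3,C11H32NO2Si2
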