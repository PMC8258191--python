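method_id,target_taxon,functional_form,coef_a,coef_b,coef_scale,length_unit,mass_unit,note
calanus_i,Calanus spp.,power,0.006458,3.9,,mm,mg,C. finmarchicus; North Atlantic and North Sea
calanus_ii,Calanus spp.,log_linear,0.735,-2.5,,mm,mg,C. finmarchicus + C. glacialis; Greenland Sea
calanus_iii,Calanus spp.,power_scaled,0.0084,3.4333,0.9,mm,mg,C. finmarchicus + C. glacialis; Nansen Basin; AFDW:DW 0.9 adjustment
oithona_i,Oithona spp.,fixed,3.0,,,um,ug,fixed individual dry weight; Svalbard usage
oithona_ii,Oithona spp.,log_log,1.84,-4.84,,um,ug,O. similis; Inland Sea of Japan
oithona_iii,Oithona spp.,log_log,0.766,-2.20,,um,ug,O. brevicornis; Inland Sea of Japan
oithona_iv,Oithona spp.,power,3.405e-10,3.643,,um,ug,O. hebes; Cananeia Lagoon (Brazil)
oithona_v,Oithona spp.,power,2.513e-11,4.113,,um,ug,O. oswaldocruzi; Cananeia Lagoon (Brazil)
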