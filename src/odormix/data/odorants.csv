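abbreviation,name,cas,family,threshold_mg_m3
EA,ethyl acetate,141-78-6,ester,0.276
BA,butyl acetate,123-86-4,ester,0.085
EB,ethyl butyrate,105-54-4,ester,0.053
PA,propionaldehyde,123-38-6,aldehyde,0.0406
VA,n-valeraldehyde,110-62-3,aldehyde,0.0205
HEP,n-heptaldehyde,117-71-7,aldehyde,0.0260
B,benzene,71-43-2,aromatic,2.53
T,toluene,108-88-3,aromatic,1.43
E,ethylbenzene,100-41-4,aromatic,0.45
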