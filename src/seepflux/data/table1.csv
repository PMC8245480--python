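name,seep_area_m2,rock_area_m2,printed_flux_mol_yr,printed_flux_se_mol_yr,reference
Hydrate Ridge,3.97E+05,3.00E+05,4.94E+06,9.03E+05,"Teichert et al., 2005"
Costa Rica Margin,4.91E+05,2.40E+05,3.95E+06,7.22E+05,"Klaucke et al., 2008"
Chilean Continental Margin,2.06E+06,7.36E+05,1.21E+07,2.21E+06,"Klaucke et al., 2012"
New Zealand Omakere Ridge,1.28E+06,4.77E+05,7.85E+06,1.44E+06,"Jones et al., 2010"
New Zealand Wairarapa Area,1.43E+05,4.02E+04,6.62E+05,1.21E+05,"Klaucke et al., 2010"
Santa Monica Basin,5.02E+05,3.94E+05,6.84E+06,1.19E+06,"Paull et al., 2008"
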