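# Published regional decomposition of the 1985-2017 rise in age-standardised
# population mean BMI: posterior-mean absolute contributions (kg m^-2) of the
# rural, urban and urbanisation components, and the printed integer
# percentage contributions (blank where suppressed as NR because the total
# regional change was below 0.5 kg m^-2).  Used as worked-example inputs for
# the point-mode percentage calculation; absolute values are printed to two
# decimals, so a few derived percentages can differ by one integer from the
# printed ones (see docs/methods.md).
region,sex,rural_abs,urban_abs,urbanization_abs,rural_pct,urban_pct,urbanization_pct
central_asia_middle_east_north_africa,men,1.30,1.33,0.09,48,49,3
central_asia_middle_east_north_africa,women,1.96,1.31,0.06,59,39,2
east_southeast_asia,men,1.99,0.66,0.33,67,22,11
east_southeast_asia,women,1.81,0.47,0.18,73,19,7
latin_america_caribbean,men,0.86,1.73,0.17,31,63,6
latin_america_caribbean,women,1.29,2.01,0.06,38,60,2
oceania,men,2.24,0.24,0.00,90,10,0
oceania,women,2.41,0.53,0.00,81,19,0
south_asia,men,1.99,0.20,0.12,86,8,5
south_asia,women,2.18,0.36,0.19,80,13,7
sub_saharan_africa,men,1.14,0.39,0.23,64,22,14
sub_saharan_africa,women,1.37,0.58,0.45,57,24,19
central_eastern_europe,men,0.59,1.10,0.00,35,65,0
central_eastern_europe,women,0.14,0.13,-0.02,,,
high_income_asia_pacific,men,0.48,1.15,-0.04,31,72,-2
high_income_asia_pacific,women,0.12,-0.02,-0.10,,,
high_income_western,men,0.58,1.80,-0.01,24,76,0
high_income_western,women,0.39,1.44,0.00,21,79,0
world,men,1.24,0.65,0.30,57,30,14
world,women,1.22,0.56,0.25,60,28,13
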