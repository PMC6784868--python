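# WHO world standard population shares by age group (percent).
# Single-year shares for ages 18 and 19 are one fifth of the 15-19 group;
# the 85+ share is folded into the open-ended top group (80-84 here).
# Weights are renormalised over the adult groups at load time.
age_lo,age_hi,share
18,18,1.694
19,19,1.694
20,24,8.22
25,29,7.93
30,34,7.61
35,39,7.15
40,44,6.59
45,49,6.04
50,54,5.37
55,59,4.55
60,64,3.72
65,69,2.96
70,74,2.21
75,79,1.52
80,84,1.54
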