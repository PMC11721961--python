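system,dG_active_barrier,dG_inactive_barrier,Ki_prime,IC50_uM,dG_exp
apo-SHP2,70.28,67.00,,,
RMC-4550,131.90,29.03,9.00e-35,0.00155,-16.67
IACS-13909,126.81,20.05,1.07e-29,,-10.71
SHP389,99.19,31.74,1.84e-34,,-8.57
SHP099,126.93,82.78,1.05e-30,,-6.85
Compound 7,120.76,111.03,5.14e-26,0.181,-4.41
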