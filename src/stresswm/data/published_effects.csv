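# Published study-level effects (mean difference, SEM) feeding the chains.
# outcome units: percent_correct in percentage points, rt_ms in milliseconds.
# source=printed: value printed in the original report's tables.
# source=reconstructed: the age/rt likelihood columns were typeset garbled in
#   the original tables; these were recovered by inverting the conjugate
#   update from the printed prior/posterior sequence (precision subtraction)
#   and reproduce the printed posteriors and Bayes factors.
contrast,outcome,step,study_label,mean_diff,sem,n,source
age,percent_correct,0,Marshall,4.83,1.64,60,printed
age,percent_correct,1,Study 1,4.35,2.42,40,printed
age,percent_correct,2,Study 2A,1.29,2.12,58,printed
age,percent_correct,3,Study 2B,-1.98,2.06,58,printed
age,rt_ms,0,Marshall,-441.28,109.07,46,printed
age,rt_ms,1,Study 1,-155.70,71.44,40,reconstructed
age,rt_ms,2,Study 2A,-88.82,60.03,58,reconstructed
age,rt_ms,3,Study 2B,-75.51,46.80,58,reconstructed
stress,percent_correct,0,Marshall,3.50,1.62,60,printed
stress,percent_correct,1,Study 1,5.77,2.35,40,printed
stress,percent_correct,2,Study 2A,3.79,2.2,58,printed
stress,percent_correct,3,Study 2B,-1.18,2.07,58,printed
stress,rt_ms,0,Marshall,62.33,158.09,46,printed
stress,rt_ms,1,Study 1,-146.53,72.13,40,printed
stress,rt_ms,2,Study 2A,64.12,59.29,58,printed
stress,rt_ms,3,Study 2B,2.63,48.69,58,printed
interaction,percent_correct,0,Marshall,-12.55,2.85,60,printed
interaction,percent_correct,1,Study 1,1.53,4.65,40,printed
interaction,percent_correct,2,Study 2A,-1.54,4.23,58,printed
interaction,percent_correct,3,Study 2B,6.39,4.23,58,printed
interaction,rt_ms,0,Marshall,-47.75,254.72,46,printed
interaction,rt_ms,1,Study 1,104.80,138.22,40,printed
interaction,rt_ms,2,Study 2A,93.36,123.58,58,printed
interaction,rt_ms,3,Study 2B,-19.04,96.41,58,printed
stress_within_young,percent_correct,0,Marshall,-2.39,1.88,60,printed
stress_within_young,percent_correct,1,Study 1,6.13,3.12,40,printed
stress_within_young,percent_correct,2,Study 2A,3.16,3.06,58,printed
stress_within_young,percent_correct,3,Study 2B,1.79,3.60,58,printed
stress_within_young,rt_ms,0,Marshall,-87.32,78.59,46,printed
stress_within_young,rt_ms,1,Study 1,-111.89,109.76,40,printed
stress_within_young,rt_ms,2,Study 2A,121.94,82.12,58,printed
stress_within_young,rt_ms,3,Study 2B,-25.33,65.47,58,printed
stress_within_older,percent_correct,0,Marshall,9.39,2.01,60,printed
stress_within_older,percent_correct,1,Study 1,5.39,3.26,40,printed
stress_within_older,percent_correct,2,Study 2A,4.53,2.83,58,printed
stress_within_older,percent_correct,3,Study 2B,-4.15,2.14,58,printed
stress_within_older,rt_ms,0,Marshall,102.87,209.13,46,printed
stress_within_older,rt_ms,1,Study 1,-185.66,75.62,40,printed
stress_within_older,rt_ms,2,Study 2A,-2.73,93.16,58,printed
stress_within_older,rt_ms,3,Study 2B,30.59,69.27,58,printed
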