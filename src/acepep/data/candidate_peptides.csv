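sequence,abundance,confidence,binding_energy,score_a,score_b,score_c,total,inhibition_pct
KNYPF,1.58e10,418.0,-8.4,95.05,99.09,88.42,94.27,78.56
VEIPH,1.41e10,420.6,-8.6,84.53,99.72,90.53,90.89,75.78
KPYPDWS,1.61e10,420.2,-7.7,96.26,99.62,81.05,92.71,71.55
IDFDF,1.50e10,416.2,-9.5,90.02,98.67,100.00,95.61,87.04
FDYDFG,1.60e10,412.5,-6.8,95.82,97.80,71.58,89.14,61.15
SFHRL,1.67e10,421.8,-8.8,100.00,100.0,92.63,97.79,81.43
DVNFR,1.56e10,419.8,-8.9,93.41,99.53,93.68,95.32,83.26
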