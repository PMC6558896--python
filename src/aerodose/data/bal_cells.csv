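endpoint,particle,day,dose_ug,mean,sem,n
neutrophils,CAP,1,0,2.84,0.89,6
neutrophils,CAP,1,6,6.43,0.88,6
neutrophils,CAP,1,18,36.72,10.00,6
neutrophils,CAP,1,54,101.09,11.07,6
neutrophils,JEP,1,0,2.84,0.89,6
neutrophils,JEP,1,6,6.29,3.00,6
neutrophils,JEP,1,18,25.89,8.57,6
neutrophils,JEP,1,54,110.88,14.66,6
neutrophils,NIST2975,1,0,2.84,0.89,6
neutrophils,NIST2975,1,18,1.67,0.46,6
neutrophils,NIST2975,1,54,25.57,5.82,6
neutrophils,NIST2975,1,162,148.46,9.74,6
total_cells,CAP,1,0,56.43,6.42,6
total_cells,CAP,1,6,53.32,9.87,6
total_cells,CAP,1,18,82.22,11.96,6
total_cells,CAP,1,54,147.50,10.64,6
total_cells,JEP,1,0,56.43,6.42,6
total_cells,JEP,1,6,66.37,21.58,6
total_cells,JEP,1,18,91.02,9.67,6
total_cells,JEP,1,54,160.50,17.40,6
total_cells,NIST2975,1,0,56.43,6.42,6
total_cells,NIST2975,1,18,47.92,7.36,6
total_cells,NIST2975,1,54,61.50,9.22,6
total_cells,NIST2975,1,162,191.33,11.98,6
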