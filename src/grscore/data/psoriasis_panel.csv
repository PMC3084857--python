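snp_id,chrom,gene,risk_allele,nonrisk_allele,odds_ratio,case_freq,control_freq
rs11209026,1,IL23R,G,A,1.61,0.961,0.938
rs4112788,1,LCE3C/3D,C,T,1.37,0.701,0.635
rs20541,5,IL13,C,T,1.06,0.813,0.806
rs17728338,5,TNIP1/ANXA6,A,G,1.94,0.109,0.061
rs3213094,5,IL12B,G,A,1.59,0.853,0.784
rs6908425,6,CDKAL1,C,T,1.22,0.823,0.792
rs10484554,6,HLA-C,T,C,3.07,0.351,0.158
rs610604,6,TNFAIP3,C,T,1.12,0.364,0.336
rs2066808,12,IL23A/STAT2,T,C,1.82,0.955,0.920
rs6125829,20,ZNF313,G,T,1.13,0.646,0.616
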