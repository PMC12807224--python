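dataset,cell_type,n_droplets,n_genes,doublet_rate_pct,annotation
pbmc-ch,pbmc,15272,21639,16.66,cell hashing
cline-ch,"HEK293T, K562, KG1, THP1",7954,25221,18.42,cell hashing
mkidney-ch,mouse kidney,21179,18940,37.31,cell hashing
hm-12k,"HEK293T, NIH3T3",12820,15106,5.69,species mixture
hm-6k,"HEK293T, NIH3T3",6806,15080,2.51,species mixture
pbmc-1A-dm,pbmc,3298,15170,3.64,demuxlet
pbmc-1B-dm,pbmc,3790,15143,3.43,demuxlet
pbmc-1C-dm,pbmc,5270,15865,6.00,demuxlet
pbmc-2ctrl-dm,pbmc,13913,17584,11.49,demuxlet
pbmc-2stim-dm,pbmc,13916,17315,11.72,demuxlet
J293t-dm,"jurkat, HEK293T",500,16374,8.40,demuxlet
pdx-MULTI,"human breast cancer, mouse immune",10296,14025,12.79,MULTI-seq
HMEC-orig-MULTI,HMEC,26426,24199,13.50,MULTI-seq
HMEC-rep-MULTI,HMEC,10580,17473,31.02,MULTI-seq
HEK-HMEC-MULTI,"HEK293T, HMEC",10641,23982,4.60,MULTI-seq
nuc-MULTI,"nuclei (HEK293T, MEF, Jurkat)",5578,21490,8.52,MULTI-seq
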