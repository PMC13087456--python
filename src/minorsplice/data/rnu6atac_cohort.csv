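# Clinical table for the RNU6ATAC cohort (7 individuals, 4 families).
# Sentinels: N/A = not applicable, N/R = not recorded.
# immune_features / additional_features are '; '-separated lists; N/R when the cell was not recorded.
# allele*_n are transcript-level HGVS n. descriptions (1-based on the snRNA, GenBank NR_023344.1);
# allele*_g are genomic HGVS g. descriptions (Hg38, GenBank NC_000009.12).
individual_id,family_id,gene,sex,genetic_ancestry,age_last_assessment_years,deceased,bw_z,age_dx_weeks,glucose_dx_mmol_l,hba1c_mmol_mol,insulin_dose_u_kg_day,autoantibodies,immune_features,microcephaly,developmental_delay,additional_features,zygosity,chromosome,allele1_n,allele1_g,allele2_n,allele2_g
A.II-1,A,RNU6ATAC,F,EAS,0.3,yes,-2.26,13,28.3,N/A,N/A,N/A,sepsis; atopic dermatitis; B cell lymphopenia; low IgA; low IgG; hypothyroidism,no,N/A,diarrhea; facial dysmorphism,homozygous,chr9,6G>A,134164559C>T,6G>A,134164559C>T
A.II-2,A,RNU6ATAC,F,EAS,0.3,yes,-3.17,11,33,N/A,N/A,N/A,B cell lymphopenia; hypothyroidism,no,N/A,jaundice; elevated unconjugated bilirubin,homozygous,chr9,6G>A,134164559C>T,6G>A,134164559C>T
B.II-1,B,RNU6ATAC,M,SAS,0.3,yes,-1.72,17,41,N/A,1.5,"GADA positive (52, >11)",agammaglobulinemia,no,N/A,none reported,homozygous,chr9,71C>T,134164494G>A,71C>T,134164494G>A
C.II-1,C,RNU6ATAC,M,MID,5,no,N/R,36,N/R,N/R,N/R,N/R,hypogammaglobulinemia; immunodeficiency,N/R,N/R,epiphyseal dysplasia; elevated liver enzymes,homozygous,chr9,43G>A,134164522C>T,43G>A,134164522C>T
D.II-1,D,RNU6ATAC,M,MID,4,no,0.06,5,25,111,0.7,negative,thyroiditis (1.5 years); alopecia (3.5 years),no,no,none reported,compound_het,chr9,4T>C,134164561A>G,68C>A,134164497G>T
D.II-2,D,RNU6ATAC,F,MID,14,no,0.06,110,25,108,N/R,negative,N/R,no,no,severe growth retardation (not GH deficient); delayed puberty,compound_het,chr9,4T>C,134164561A>G,68C>A,134164497G>T
D.II-3,D,RNU6ATAC,M,MID,9,no,N/R,260,N/R,118,N/R,"GADA positive (98, >11)",alopecia and vitiligo (4.5 years); thyroiditis (4 years),no,no,none reported,compound_het,chr9,4T>C,134164561A>G,68C>A,134164497G>T
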