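# Clinical table for the RNU4ATAC cohort (12 unrelated individuals).
# Sentinels: N/A = not applicable, N/R = not recorded.
# allele*_n are transcript-level HGVS n. descriptions (1-based on the snRNA, GenBank NR_023343.1);
# allele*_g are genomic HGVS g. descriptions (Hg38, GenBank NC_000002.12).
individual_id,family_id,gene,sex,genetic_ancestry,age_last_assessment_years,deceased,bw_z,age_dx_weeks,glucose_dx_mmol_l,hba1c_mmol_mol,insulin_dose_u_kg_day,autoantibodies,immune_features,microcephaly,developmental_delay,additional_features,zygosity,chromosome,allele1_n,allele1_g,allele2_n,allele2_g
1.II-1,1,RNU4ATAC,F,MID,6.8,yes,-3.07,20,38.1,64,1.5,negative,recurrent infections; IgA deficiency,yes,yes,hip dislocation; muscle weakness; respiratory failure; seizures,homozygous,chr2,51G>A,121530930G>A,51G>A,121530930G>A
2.II-1,2,RNU4ATAC,F,OTH,12,yes,-3.04,6,25,73,3,negative,recurrent infections; myelodysplastic syndrome,yes,yes,triple X syndrome; insulin resistance; muscle weakness; dysmorphic features; growth retardation; diabetic nephropathy,homozygous,chr2,46G>A,121530925G>A,46G>A,121530925G>A
3.II-1,3,RNU4ATAC,F,MID,0.9,no,-4.39,1,21,N/A,0.82,N/A,N/R,yes,N/R,facial dysmorphism; peaked nose; small head; downward slanting palpebral fissures; small mandible,homozygous,chr2,36T>G,121530915T>G,36T>G,121530915T>G
4.II-1,4,RNU4ATAC,F,EAS,1.4,yes,-4.29,8,20.3,47.5,1.5,negative,N/R,yes,yes,muscle weakness; corpus callosum agenesis; bilateral knee dislocation,compound_het,chr2,51G>A,121530930G>A,55G>A,121530934G>A
5.II-1,5,RNU4ATAC,F,OTH,8.7,no,-1.71,102,39,43.2,0.8,"GADA positive (93, >11)",raised immature granulocytes,N/R,yes,muscle weakness; epilepsy; cholestasis and direct hyperbilirubinemia (resolved); ASD; congenital cataracts; sensorineural hearing loss,compound_het,chr2,48G>A,121530927G>A,60G>A,121530939G>A
6.II-1,6,RNU4ATAC,F,AFR,11,no,-0.97,110,32,50,0.72,"GADA positive (1,581, >11)",severe atopic dermatitis; autoimmune hypothyroidism,yes,yes,loose skin folds; laryngomalacia tracheomalacia; multiple epiphyseal dysplasia; high myopia; alternating exotropia,compound_het,chr2,13C>T,121530892C>T,51G>A,121530930G>A
7.II-1,7,RNU4ATAC,F,MID,5.9,no,1.14,51,N/R,61,N/R,"GADA positive (657, >11)",N/R,yes,yes,high arched palate; abnormal object eye tracking; dysmorphic features,homozygous,chr2,55G>A,121530934G>A,55G>A,121530934G>A
8.II-1,8,RNU4ATAC,F,OTH,9.5,no,-2.15,26,33,N/A,1.2,N/A,recurrent infections,yes,yes,"epilepsy; musculoskeletal abnormalities; premature menarche (9 years, suppressed); mitral valve prolapse; older sister affected with microcephaly and diabetes (11 m), died age 15 m",homozygous,chr2,55G>A,121530934G>A,55G>A,121530934G>A
9.II-1,9,RNU4ATAC,F,EAS,1.0,no,-1.56,40,55,57,1.0,N/A,N/R,yes,N/R,N/R,homozygous,chr2,55G>A,121530934G>A,55G>A,121530934G>A
10.II-1,10,RNU4ATAC,F,MID,0.8,no,-0.98,20,33,N/A,1,N/A,N/R,N/R,N/R,N/R,homozygous,chr2,16G>A,121530895G>A,16G>A,121530895G>A
11.II-1,11,RNU4ATAC,F,SAS,1.3,no,-0.14,20,44,90,1.4,N/A,N/R,yes,yes,dysmorphism,homozygous,chr2,55G>A,121530934G>A,55G>A,121530934G>A
12.II-1,12,RNU4ATAC,M,MID,0.4,no,-2.71,1,24,45,0.5,N/A,autoimmune hypothyroidism,N/R,N/R,muscle weakness,compound_het,chr2,17G>A,121530896G>A,36T>C,121530915T>C
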