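# Published reference panel of urinary col1a1 fragments (literature-reported).
# Long format: one row per (fragment, covariate) pair from the three top-10
# rankings: Spearman rho vs eGFR and age (full cohort), vs age-corrected eGFR,
# and vs age within the eGFR-matched sub-cohort.  Coordinates are 1-based
# inclusive on the full precursor (signal peptide = 1-22, mature chain 162-1218).
# Lowercase p = hydroxyproline, lowercase m = methionine sulfoxide.
# p_bh = Benjamini-Hochberg adjusted p-value as printed (0 = below double
# precision in the source).
panel	rank	modified_sequence	start	stop	rho	p_bh
egfr	1	ADGQpGAKGEpGDAGAKGDAGpPGPAGPAGPpGPIG	819	854	0.61	0
egfr	2	IGPpGPAGApGDKGESGPSGPAGPTG	769	794	0.59	0
egfr	3	LTGPIGppGPAGAPGDKGESGPSGPAGPTG	765	794	0.57	0
egfr	4	pPGADGQPGAKGEpGDAGAKGDAGppGPAGPAGPPGPIG	816	854	0.55	0
egfr	5	PpGPAGFAGPPGADGQPGAKGEpGDAGAKGDAGPPGPAGP	807	846	0.54	0
egfr	6	LDGAKGDAGPAGPKGEpGSpGENGApG	273	299	0.50	0
egfr	7	TGPIGpPGPAGAPGDKGESGpSGPAGPTG	766	794	0.50	0
egfr	8	GPpGADGQPGAKGEpGDAGAKGDAGPPGpAGPAGPPGpIG	815	854	0.50	1.02e-305
egfr	9	GADGQpGAKGEpGDAGAKGDAGPPGPAGPAGPpGPIG	818	854	0.48	1.42e-291
egfr	10	NGDDGEAGKPGRpGERGPpGPQG	229	251	0.48	3.41e-279
age	1	ADGQpGAKGEpGDAGAKGDAGpPGPAGPAGPpGPIG	819	854	-0.39	1.14e-180
age	2	IGPpGPAGApGDKGESGPSGPAGPTG	769	794	-0.38	7.36e-172
age	3	LTGPIGppGPAGAPGDKGESGPSGPAGPTG	765	794	-0.36	1.19e-153
age	4	pPGADGQPGAKGEpGDAGAKGDAGppGPAGPAGPPGPIG	816	854	-0.34	2.69e-132
age	5	PpGPAGFAGPPGADGQPGAKGEpGDAGAKGDAGPPGPAGP	807	846	-0.31	7.21e-110
age	6	LDGAKGDAGPAGPKGEpGSpGENGApG	273	299	-0.38	5.05e-169
age	7	TGPIGpPGPAGAPGDKGESGpSGPAGPTG	766	794	-0.29	3.64e-94
age	8	GPpGADGQPGAKGEpGDAGAKGDAGPPGpAGPAGPPGpIG	815	854	-0.35	3.06e-142
age	9	GADGQpGAKGEpGDAGAKGDAGPPGPAGPAGPpGPIG	818	854	-0.27	6.08e-81
age	10	NGDDGEAGKPGRpGERGPpGPQG	229	251	-0.25	3.26e-69
age_corrected_egfr	1	ADGQpGAKGEpGDAGAKGDAGpPGPAGPAGPpGPIG	819	854	0.44	2.84e-232
age_corrected_egfr	2	PpGPAGFAGPPGADGQPGAKGEpGDAGAKGDAGPPGPAGP	807	846	0.41	1.64e-202
age_corrected_egfr	3	IGPpGPAGApGDKGESGPSGPAGPTG	769	794	0.41	1.05e-201
age_corrected_egfr	4	PGPAGPPGEAGKPGEQGVPGDLGAPGPSGARG	646	677	-0.41	9.43e-197
age_corrected_egfr	5	LTGPIGppGPAGAPGDKGESGPSGPAGPTG	765	794	0.40	1.24e-191
age_corrected_egfr	6	pPGADGQPGAKGEpGDAGAKGDAGppGPAGPAGPPGPIG	816	854	0.40	4.80e-186
age_corrected_egfr	7	TGPIGpPGPAGAPGDKGESGpSGPAGPTG	766	794	0.38	1.26e-168
age_corrected_egfr	8	NGDDGEAGKPGRpGERGPpGPQG	229	251	0.37	4.25e-163
age_corrected_egfr	9	KEGGKGPRGETGPAGRpGEVGPpGPpGPAG	903	932	0.37	8.82e-160
age_corrected_egfr	10	GADGQpGAKGEpGDAGAKGDAGPPGPAGPAGPpGPIG	818	854	0.37	1.68e-158
age_in_egfr_matched	1	DAGPAGPKGEpGSpGENGApG	279	299	-0.39	2.15e-33
age_in_egfr_matched	2	LDGAKGDAGPAGPKGEpGSpGENGApG	273	299	-0.36	5.16e-29
age_in_egfr_matched	3	pGpAGEKGSpGADGPAGAP	928	946	0.36	1.10e-28
age_in_egfr_matched	4	GLPGpAGppGEAGKPGEQGVPGDLGApGP	644	672	-0.36	1.68e-28
age_in_egfr_matched	5	ADGQpGAKGEpGDAGAKGDAGPPGPAGP	819	846	-0.35	5.81e-27
age_in_egfr_matched	6	GSpGSpGPDGKTGPpGPAG	542	560	-0.35	2.43e-26
age_in_egfr_matched	7	EpGSpGENGAPGQmGPR	288	304	0.32	3.01e-22
age_in_egfr_matched	8	pPGADGQPGAKGEpGDAGAKGDAGppGPAGPAGPPGPIG	816	854	-0.29	6.76e-19
age_in_egfr_matched	9	EGSPGRDGSPGAK	1021	1033	0.28	2.41e-17
age_in_egfr_matched	10	IGPpGPAGApGDKGESGPSGPAGPTG	769	794	-0.28	4.70e-17
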