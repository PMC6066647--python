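# Described species with deep (>2%) intraspecific divergence: maximum and
# mean intraspecific K2P distance (%), number of NJ clades and BIN / ABGD /
# bPTP cluster counts.  `flagged_cryptic` marks the rows the survey starred
# as putative cryptic species; `shares_with_nominal` marks species whose
# clusters also contain another nominal species (stated in the survey text);
# `n_labels` is the number of morphospecies the row pools (one combined row
# covers two Characidium morphospecies); `raw_max`/`raw_mean` preserve the
# printed per-label values for that combined row.
morphospecies	max_intra	mean_intra	n_clades	n_bin	n_abgd	n_bptp	flagged_cryptic	shares_with_nominal	n_labels	raw_max	raw_mean
Astyanax fasciatus	20.69	10.09	3	3	3	3	no	yes	1
Astyanax lacustris	3.35	1.67	2	2	2	2	no	yes	1
Astyanax scabripinnis	21.82	9.12	2	2	3	2	no	yes	1
Astyanax taeniatus	3.96	1.48	2	2	2	2	no	yes	1
Characidium sp./Characidium cf. timbuiense	10.17	5.51	4	4	4	4	yes	no	2	10.17/9.9	5.51/5.98
Crenicichla lacustris	21.36	10.76	2	2	2	2	yes	no	1
Hoplias malabaricus	6.7	3.27	2	2	2	2	yes	no	1
Knodus moenkhausii	3.07	1.21	1	1	2	1	no	no	1
Poecilia reticulata	14.34	9.48	2	2	2	2	no	yes	1
Prochilodus costatus	2.6	1.32	2	1	1	2	no	yes	1
Rhamdia cf. quelen	3.48	1.25	2	2	2	2	yes	no	1
Trichomycterus aff. alternatus	18.49	10.8	2	2	2	2	no	yes	1
Trichomycterus aff. immaculatus	5.84	2.23	2	2	2	2	no	yes	1
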