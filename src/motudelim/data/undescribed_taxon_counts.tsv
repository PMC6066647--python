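# Per-taxon cluster counts for the undescribed morphospecies, compiled from
# the published survey: BIN counts follow the per-cluster table; ABGD and
# Bayesian-PTP counts equal the BIN count except where the survey reported a
# method exception (Harttia sp.: 3 BIN/ABGD but a single bPTP cluster;
# Trichomycterus sp.: two of its five BIN clusters merged by ABGD).
# max_intra/mean_intra (%) are the reported deep intra-label divergences;
# blank where not reported.
morphospecies	n_bin	n_abgd	n_bptp	max_intra	mean_intra
Astyanax sp.	4	4	4	20.5
Brycon sp.	1	1	1
Characidium sp.	3	3	3	10.17	5.51
Gymnotus sp.	3	3	3	6.32
Harttia sp.	3	3	1	12.2	4.67
Hasemania sp.	1	1	1
Hisonotus sp.	1	1	1
Hypostomus sp.	1	1	1
Imparfinis sp.	1	1	1
Neoplecostomus sp.	2	2	2
Neoplecostominae	1	1	1
Pareiorhaphis sp.	2	2	2
Phalloceros sp.	1	1	1
Pimelodella sp.	1	1	1
Trichomycterus sp.	5	4	5
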