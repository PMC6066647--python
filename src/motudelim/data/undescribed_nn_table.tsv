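# Nearest-neighbour / cluster survey for undescribed (open-nomenclature)
# morphospecies of the Doce River Basin barcode reference library.
# One row per reported cluster (or per additional similarity comparison when
# the cluster column is blank).  Blank continuation cells in the original
# table are filled with the taxon label so every row is self-contained.
morphospecies	nn_species	bin	bin_classification	max_similarity
Astyanax sp.	Astyanax fasciatus	AAC5910	Discordant	99.32
Astyanax sp.	Deterodon pedri	ACJ9650	Discordant	99
Astyanax sp.	Astyanax intermedius	ACT0040	Singleton	93.32
Astyanax sp.	Astyanax fasciatus, A. bockmanni	AAY4812	Discordant	99.32
Brycon sp.	Brycon ferox	ACH8616	Concordant	100
Characidium sp.	Characidium sp.	ACS9348	Concordant	100
Characidium sp.	Characidium cf. timbuiense	ACJ1226	Discordant	100
Characidium sp.	Characidium cf. timbuiense	ACI3743	Discordant	100
Gymnotus sp.	Gymnotus carapo	AAB6216	Discordant	100
Gymnotus sp.	Gymnotus sylvius	AAB6212	Concordant	100
Gymnotus sp.	Gymnotus sp.	ACT0768	Concordant	100
Harttia sp.	Harttia sp.	ACJ1000	Singleton	100
Harttia sp.	Harttia sp.	ACI6845	Concordant	100
Harttia sp.	Harttia sp.	ACO6155	Singleton	100
Hasemania sp.	Hasemania hanseni	AAO6055	Concordant	100
Hisonotus sp.	Hisotonus sp.	ACW1732	Concordant	100
Hypostomus sp.	Hypostomus auroguttatus	AAB9690	Discordant	100
Hypostomus sp.	Hypostomus heraldoi			98.32
Hypostomus sp.	Hypostomus luetkeni			99.32
Hypostomus sp.	Hypostomus strigaticeps			99.32
Imparfinis sp.	Imparfinis minutus	AAC2103	Concordant	99.32
Imparfinis sp.	Imparfinis mirini			98.32
Neoplecostomus sp.	Neoplecostomus sp.	AAX6581	Concordant	100
Neoplecostomus sp.	Neoplecostomus sp.	ACT2675	Concordant	100
Neoplecostominae	Pareiohaphis cf. bahianus	ACC0721	Concordant	98.32
Pareiorhaphis sp.	Pareiohaphis scutula	AAX0824	Discordant	99.32
Pareiorhaphis sp.	Pareiorhaphis sp.	ACI5663	Concordant	100
Phalloceros sp.	Phalloceros sp.	AAB7265	Concordant	100
Pimelodella sp.	Pimelodella lateristriga	AAC5327	Concordant	99.32
Trichomycterus sp.	Trichomycterus aff. immaculatus/T. cf. pradensis	ACI3868	Discordant	99.32
Trichomycterus sp.	Trichomycterus aff. auroguttatus	ACJ1164	Discordant	100
Trichomycterus sp.	Trichomycterus sp.	ACJ9705	Singleton	98
Trichomycterus sp.	Trichomycterus cf. brasiliensis	ACK5393	Singleton	98.32
Trichomycterus sp.	Trichomycterus cf. brasiliensis	ACT6325	Discordant	99.8
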