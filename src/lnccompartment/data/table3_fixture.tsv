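lnc_id	relationship_with_gene	dir_heart	dir_plasma	dir_whole_blood	associated_gene_id
ENSMUST00000118506	intergenic	+	+	+
ENSMUST00000121157	intergenic	+	+	+
ENSMUST00000119799	intergenic	+	+	+
ENSMUST00000118172	intergenic	+	+	+
ENSMUST00000118572	intergenic	+	+	+
uc007qxl.1	antisense overlap	+	+	-	14088
uc007qgn.1	intergenic	+	-	-
AK082011	bidirectional	+	-	-	72401
MM9LINCRNAEXON10032-	intergenic	+	-	-
NR_024599	intergenic	+	-	-
ENSMUST00000120198	intergenic	+	-	-
ENSMUST00000156391	bidirectional	-	-	+	72151
ENSMUST00000150754	intergenic	-	-	+
ENSMUST00000152379	bidirectional	-	+	-	56397
MM9LINCRNAEXON10893+	intergenic	-	+	-
AK155808	intergenic	-	+	-
AK141702	intergenic	-	-	-
AK156805	intergenic	-	-	-
uc008uuw.1	intergenic	-	-	-
MM9LINCRNAEXON10133-	intergenic	-	-	-
AK015845	intergenic	-	-	-
uc007xrw.1	intergenic	-	-	-
NR_037610	sense overlap	-	-	-	18472
AK157007	intergenic	-	-	-
ENSMUST00000149914	bidirectional	-	-	-	83691
AK044386	intergenic	-	-	-
MM9LINCRNAEXON10681+	intergenic	-	-	-
MM9LINCRNAEXON10421-	intergenic	-	-	-
MM9LINCRNAEXON11017-	antisense	-	-	-	72543
AK156356	antisense	-	+	+	69277
uc007rjp.1	intergenic	-	+	+
AK009126	intergenic	-	+	+
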