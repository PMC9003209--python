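gene_id	chrom	start	end	strand	annotation
CsaV3_6G013600	chr6	9736464	9740433	-	Small auxin-up RNA
CsaV3_6G013610	chr6	9762144	9764899	+	Peptidyl-prolyl cis-trans isomerase FKBP5
CsaV3_6G013700	chr6	9901956	9903554	+	NAC domain
CsaV3_6G013720	chr6	9919247	9921289	+	NAC domain
CsaV3_6G013830	chr6	10022293	10025625	+	Glucan endo-1,3-beta-glucosidase
CsaV3_6G013910	chr6	10078532	10080455	-	Aquaporin PIP2-7-like
CsaV3_6G013920	chr6	10093981	10094739	+	Senescence regulator S40
CsaV3_6G013960	chr6	10156022	10160149	-	Auxin response factor
CsaV3_6G014010	chr6	10204862	10209042	-	Exosome complex component MTR3
CsaV3_6G014030	chr6	10219586	10224039	-	Zinc finger
CsaV3_6G014150	chr6	10290872	10297455	+	P-loop NTPase domain
CsaV3_6G014230	chr6	10347201	10348923	-	Heavy metal-associated domain
CsaV3_6G014250	chr6	10365575	10371237	-	Lysine methyltransferase
CsaV3_6G014260	chr6	10365754	10367581	+	Alpha-L-fucosidase 1
CsaV3_6G014270	chr6	10371432	10374387	+	Uncharacterized protein
CsaV3_6G014290	chr6	10382370	10385069	-	Glucuronoxylan glucuronosyltransferase
CsaV3_6G014380	chr6	10432200	10442898	-	Uncharacterized protein
CsaV3_6G014740	chr6	10700897	10703058	-	Histone-lysine N-methyltransferase
CsaV3_6G014750	chr6	10709780	10710073	+	Uncharacterized protein
CsaV3_6G014760	chr6	10710135	10711415	-	Prephenate dehydratase
CsaV3_6G015120	chr6	10976098	10977090	-	Uncharacterized protein
CsaV3_6G015130	chr6	10978344	10982661	-	Protein trichome birefringence-like 11
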