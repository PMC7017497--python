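species	conjugation	ba_class	internal_standard	merged_with
TCA	tauro	primary	D4-TCA	
TaMCA	tauro	primary	D4-TCA	
TbMCA	tauro	primary	D4-TCA	
TwMCA	tauro	secondary	D4-TCA	
THCA	tauro	primary	D4-TCA	
TCDCA	tauro	primary	D4-TDCA	
TDCA	tauro	secondary	D4-TDCA	
TUDCA	tauro	secondary	D4-TDCA	
TLCA	tauro	secondary	D4-TDCA	
GCA	glyco	primary	D4-GCA	
GHCA	glyco	primary	D4-GCA	
GCDCA	glyco	primary	D4-GCDCA	
GDCA	glyco	secondary	D4-GDCA	
GHDCA	glyco	secondary	D4-GDCA	
GUDCA	glyco	secondary	D4-GUDCA	
GLCA	glyco	secondary	D4-GLCA	
CA	unconjugated	primary	D4-CA	
aMCA	unconjugated	primary	D4-CA	
bMCA	unconjugated	primary	D4-CA	
HCA	unconjugated	primary	D4-CA	
CDCA	unconjugated	primary	D4-GCDCA	
wMCA	unconjugated	secondary	D4-CA	
DCA	unconjugated	secondary	D4-DCA	
MDCA	unconjugated	secondary	D4-DCA	
UDCA	unconjugated	secondary	D4-GUDCA	HDCA
HDCA	unconjugated	secondary	D4-GUDCA	UDCA
LCA	unconjugated	secondary	D4-GLCA	
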