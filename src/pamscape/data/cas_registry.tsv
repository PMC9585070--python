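# Curated registry of class-2 CRISPR effector nucleases and the PAMs
# reported as efficient in their primary characterizations.  Edit or
# replace this table to analyse a different enzyme panel.
#
# Columns (tab-separated):
#   name  cas_type  orientation  pams (comma-sep)  ranking_pams (comma-sep; '-' = all)  reference
#
# name	cas_type	orientation	pams	ranking_pams	reference
SpCas9	Cas9	downstream	NGG	-	Jinek et al. 2012
SpCas9-VQR	Cas9	downstream	NGA	-	Kleinstiver et al. 2015
EQR-SpCas9	Cas9	downstream	NGAG	-	Kleinstiver et al. 2015
VRER-SpCas9	Cas9	downstream	NGCG	-	Kleinstiver et al. 2015
SpCas9-NG	Cas9	downstream	NG	-	Nishimasu et al. 2018
xCas9	Cas9	downstream	NG,GAA,GAT	NG	Hu et al. 2018
SpG	Cas9	downstream	NGN	-	Walton et al. 2020
SpRY	Cas9	downstream	NRN,NYN	-	Walton et al. 2020
SaCas9	Cas9	downstream	NNGRRT	-	Ran et al. 2015
KKH-SaCas9	Cas9	downstream	NNNRRT	-	Kleinstiver et al. 2015
St1Cas9	Cas9	downstream	NNAGAAW	-	Deveau et al. 2008
St3Cas9	Cas9	downstream	NGGNG	-	Horvath et al. 2008
NmeCas9	Cas9	downstream	NNNNGATT	-	Hou et al. 2013
CjCas9	Cas9	downstream	NNNNRYAC	-	Kim et al. 2017
ScCas9	Cas9	downstream	NNG	-	Chatterjee et al. 2018
iSpyMacCas9	Cas9	downstream	NAA	-	Chatterjee et al. 2020
AsCas12a	Cas12a	upstream	TTTV	-	Zetsche et al. 2015
LbCas12a	Cas12a	upstream	TTTV	-	Zetsche et al. 2015
enAsCas12a	Cas12a	upstream	TTYN,VTTV,TRTV	-	Kleinstiver et al. 2019
RR-AsCas12a	Cas12a	upstream	TYCV	-	Gao et al. 2017
RVR-AsCas12a	Cas12a	upstream	TATV	-	Gao et al. 2017
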