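roi_label	network	role
Un_01	Un	cortical
Un_02	Un	cortical
DMN_01	DMN	cortical
DMN_02	DMN	cortical
DMN_03	DMN	cortical
DMN_04	DMN	cortical
DMN_05	DMN	cortical
FPN_01	FPN	cortical
FPN_02	FPN	cortical
FPN_03	FPN	cortical
FPN_04	FPN	cortical
REW_01	REW	cortical
REW_02	REW	cortical
DAN_01	DAN	cortical
DAN_02	DAN	cortical
DAN_03	DAN	cortical
VAN_01	VAN	cortical
VAN_02	VAN	cortical
VAN_03	VAN	cortical
SAL_01	SAL	cortical
SAL_02	SAL	cortical
SAL_03	SAL	cortical
CON_01	CON	cortical
CON_02	CON	cortical
CON_03	CON	cortical
CON_04	CON	cortical
CON_05	CON	cortical
VIS_01	VIS	cortical
VIS_02	VIS	cortical
VIS_03	VIS	cortical
VIS_04	VIS	cortical
VIS_05	VIS	cortical
VIS_06	VIS	cortical
dSMN_01	dSMN	cortical
dSMN_02	dSMN	cortical
dSMN_03	dSMN	cortical
dSMN_04	dSMN	cortical
lSMN_01	lSMN	cortical
lSMN_02	lSMN	cortical
lSMN_03	lSMN	cortical
lSMN_04	lSMN	cortical
AUD_01	AUD	cortical
AUD_02	AUD	cortical
AUD_03	AUD	cortical
PMN_01	PMN	cortical
PMN_02	PMN	cortical
MTL_01	MTL	cortical
MTL_02	MTL	cortical
THAL_01	THAL_DMN	thalamic
THAL_02	THAL_DMN	thalamic
THAL_03	THAL_VIS	thalamic
THAL_04	THAL_VIS	thalamic
THAL_05	THAL_CON	thalamic
THAL_06	THAL_CON	thalamic
THAL_07	THAL_CON	thalamic
THAL_08	THAL_CON	thalamic
THAL_09	THAL_lSMN	thalamic
THAL_10	THAL_lSMN	thalamic
THAL_11	THAL_dSMN	thalamic
THAL_12	THAL_dSMN	thalamic
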