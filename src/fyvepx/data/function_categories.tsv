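domain	category
PH	Signal transduction mechanisms
RhoGEF	Signal transduction mechanisms
PIP5K	Signal transduction mechanisms
RUN	Signal transduction mechanisms
DEP	Signal transduction mechanisms
PDEase_I	Signal transduction mechanisms
Arm	Signal transduction mechanisms
Arrestin_N	Signal transduction mechanisms
SH2	Signal transduction mechanisms
Arrestin_C	Signal transduction mechanisms
Miro	Signal transduction mechanisms
NB-ARC	Signal transduction mechanisms
Ras	Signal transduction mechanisms
TIR	Signal transduction mechanisms
zf-TRAF	Signal transduction mechanisms
RGS	Signal transduction mechanisms
PB1	Signal transduction mechanisms
C2	Signal transduction mechanisms
PI3K_C2	Signal transduction mechanisms
RA	Signal transduction mechanisms
FHA	Signal transduction mechanisms
PDZ	Signal transduction mechanisms
Pkinase_C	Signal transduction mechanisms
RhoGAP	Signal transduction mechanisms
IQ	Signal transduction mechanisms
CH	Signal transduction mechanisms
VHS	Intracellular trafficking, secretion, and vesicular transport
EMP24_GP25L	Intracellular trafficking, secretion, and vesicular transport
Rab5-bind	Intracellular trafficking, secretion, and vesicular transport
Zf-RanBP	Intracellular trafficking, secretion, and vesicular transport
Rabaptin	Intracellular trafficking, secretion, and vesicular transport
Vps5	Intracellular trafficking, secretion, and vesicular transport
Nexin_C	Intracellular trafficking, secretion, and vesicular transport
Sorting_nexin	Intracellular trafficking, secretion, and vesicular transport
MIT	Intracellular trafficking, secretion, and vesicular transport
PI3Ka	Intracellular trafficking, secretion, and vesicular transport
SNARE	Intracellular trafficking, secretion, and vesicular transport
Kinesin	Intracellular trafficking, secretion, and vesicular transport
VPS9	Intracellular trafficking, secretion, and vesicular transport
BAR	Intracellular trafficking, secretion, and vesicular transport
SRPRB	Intracellular trafficking, secretion, and vesicular transport
TBC	Intracellular trafficking, secretion, and vesicular transport
Cpn60_TCP1	Chaperone
AAA	Chaperone
RCC1	Cell cycle control, cell division, chromosome partitioning
DZC	Cell cycle control, cell division, chromosome partitioning
Septin	Cell cycle control, cell division, chromosome partitioning
PI3K_rbd	Cell cycle control, cell division, chromosome partitioning
PH	Cytoskeleton
WH2	Cytoskeleton
SH3_1	Cytoskeleton
SH3_2	Cytoskeleton
SH3_3	Cytoskeleton
FERM_M	Cytoskeleton
CAP_GLY	Cytoskeleton
CH	Cytoskeleton
Zn_clus	Transcription
Ribosomal_L1	Translation
L15	Translation
Ribosomal_L15	Translation
tRNA_anti	Translation
p47_phox_C	Defence mechanisms
GBP	Defence mechanisms
Sulfate_transp	Inorganic ion transport
WD40	Protein-protein interaction
UIM	Protein-protein interaction
Ank	Protein-protein interaction
zf-C3HC4	Protein-protein interaction
BTB	Protein-protein interaction
TPR_1	Protein-protein interaction
LRR_1	Protein-protein interaction
LRR_3	Protein-protein interaction
PAN_1	Protein-protein interaction
WW	Protein-protein interaction
zf_AN1	Protein-protein interaction
Pkinase	Catalytic
Glyco_transf_28	Catalytic
PI3_PI4_kinase	Catalytic
Abhydrolase_3	Catalytic
Glyco_tran_28_C	Catalytic
Lipase_GDSL	Catalytic
Orn_Arg_deC_N	Catalytic
Pkinase_Tyr	Catalytic
Myotub-related	Catalytic
PLDc	Catalytic
4HBT	Catalytic
ADH_N	Catalytic
ADH_zinc_N	Catalytic
AhpC-TSA	Catalytic
rve	Catalytic
glutaminase	Catalytic
Glyco_hydro_18	Catalytic
Proteasome	Catalytic
Radical_SAM	Catalytic
RmlD_sub_bind	Catalytic
RNA_pol_Rpb4	Catalytic
FAD_binding_2	Metabolism
FAD_binding_4	Metabolism
Succ_DH_flav_C	Metabolism
Retrotrans_gag	Replication, recombination & repair
GRAM	General function prediction only
LysM	General function prediction only
cNMP_binding	General function prediction only
DDE	General function prediction only
FLYWCH	General function prediction only
Methyltransf_4	General function prediction only
Peptidase_A17	General function prediction only
Zf-B_box	General function prediction only
Beach	Function unclear
DUF500	Function unclear
MORN	Function unclear
MtN3_slv	Function unclear
Cupin_2	Function unclear
NIF	Function unclear
TPR_2	Function unclear
zf-DHHC	Function unclear
PXA	Function unclear
DUF399	Function unclear
CNH	Function unclear
DUF1388	Function unclear
DUF1879	Function unclear
Kelch_1	Function unclear
Kelch_2	Function unclear
LIM	Function unclear
M	Function unclear
Met_10	Function unclear
Pinin_SDK_memA	Function unclear
SAM_1	Function unclear
STAS	Function unclear
UPF0047	Function unclear
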