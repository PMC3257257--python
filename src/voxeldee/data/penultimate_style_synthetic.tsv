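# Penultimate-style rotamer table (synthetic stand-in).
# Constructed for this package with the canonical per-amino-acid group
# sizes of the published Penultimate library (e.g. 34 arginine rotamers)
# and staggered-chi modal values; sigmas are per-angle spreads in degrees.
aa	id	chi1	chi2	chi3	chi4	sig1	sig2	sig3	sig4
ARG	arg01	61.9	64.4	64.1	82.5	12.4	12.6	9.4	11.3
ARG	arg02	63.7	67.3	178.8	82.8	12.6	10.1	8.0	11.5
ARG	arg03	62.5	65.5	-66.0	83.3	12.5	13.0	12.8	12.9
ARG	arg04	59.2	178.8	62.0	83.7	8.4	12.1	8.4	11.4
ARG	arg05	61.9	179.1	181.6	86.0	12.8	12.3	11.2	10.8
ARG	arg06	61.5	177.9	-62.9	84.3	11.8	11.8	8.6	10.9
ARG	arg07	61.1	-67.8	64.8	86.3	8.7	11.6	12.6	8.3
ARG	arg08	64.8	-62.6	182.7	83.5	9.1	10.5	11.8	9.1
ARG	arg09	62.7	-67.7	-63.1	86.5	11.7	8.6	12.1	8.6
ARG	arg10	-174.7	66.3	64.0	85.1	9.3	12.7	12.2	11.9
ARG	arg11	-177.0	64.5	182.6	86.9	10.5	12.9	11.4	8.5
ARG	arg12	-178.1	67.1	-63.9	84.1	11.6	11.5	10.6	12.0
ARG	arg13	-175.8	179.8	63.6	82.4	8.6	11.0	11.0	10.7
ARG	arg14	-178.0	183.0	181.3	87.0	10.4	10.5	9.2	8.2
ARG	arg15	-178.4	182.7	-62.1	87.2	8.1	10.9	9.4	10.1
ARG	arg16	-176.3	-67.0	63.4	85.8	8.7	10.5	8.7	8.6
ARG	arg17	-176.7	-63.4	181.4	84.6	12.9	9.4	11.4	9.1
ARG	arg18	-177.8	-64.4	-66.3	84.7	9.9	8.1	10.2	8.6
ARG	arg19	-69.2	65.1	63.3	87.8	9.7	11.0	9.3	8.3
ARG	arg20	-67.6	64.4	177.5	87.6	10.5	10.9	9.1	8.7
ARG	arg21	-66.1	64.4	-63.6	86.3	9.6	9.8	10.9	8.5
ARG	arg22	-66.8	180.5	65.8	87.1	9.6	10.3	12.2	10.0
ARG	arg23	-67.5	182.9	180.4	82.8	11.5	12.3	11.8	10.1
ARG	arg24	-68.3	178.1	-62.6	85.9	8.4	11.7	12.6	9.5
ARG	arg25	-65.6	-65.8	66.9	86.7	9.5	8.6	11.3	8.5
ARG	arg26	-65.8	-66.4	182.3	86.1	10.5	9.7	12.1	11.8
ARG	arg27	-64.7	-66.0	-66.0	87.8	12.4	9.5	12.8	9.6
ARG	arg28	-178.3	181.5	177.9	180.5	9.8	12.4	10.5	8.7
ARG	arg29	-67.4	177.3	65.2	-87.1	12.5	9.2	9.9	8.3
ARG	arg30	-177.9	67.5	182.7	178.5	9.0	11.3	8.9	11.3
ARG	arg31	-177.1	-65.7	178.3	-86.6	12.8	12.4	9.4	8.5
ARG	arg32	63.3	62.0	66.6	-82.9	11.7	12.5	11.3	12.4
ARG	arg33	64.8	67.2	-67.8	-86.1	10.6	10.1	12.3	12.2
ARG	arg34	60.4	-65.6	-64.6	179.6	8.1	12.4	10.8	12.8
LYS	lys01	64.2	70.1	70.8	182.5	9.0	12.7	10.2	8.1
LYS	lys02	60.1	67.9	177.5	177.3	9.8	11.7	8.2	11.9
LYS	lys03	63.7	69.2	-70.7	181.7	11.9	10.1	10.1	8.8
LYS	lys04	63.1	177.0	65.6	178.1	9.2	9.9	11.0	8.0
LYS	lys05	62.0	181.9	183.0	177.2	10.5	12.4	8.2	10.7
LYS	lys06	60.1	180.2	-66.1	182.7	10.2	10.1	13.0	12.5
LYS	lys07	62.4	-65.9	70.6	177.5	12.5	10.4	8.0	11.6
LYS	lys08	65.0	-67.3	182.4	178.1	12.7	11.9	11.3	12.0
LYS	lys09	64.9	-67.7	-68.9	182.6	8.2	11.7	9.5	10.2
LYS	lys10	-175.3	71.0	69.3	180.3	10.5	9.9	10.8	12.1
LYS	lys11	-177.8	68.1	177.4	177.7	8.1	12.2	8.8	9.9
LYS	lys12	-175.4	67.5	-65.4	177.8	10.0	8.4	9.9	8.6
LYS	lys13	-176.2	177.8	65.3	179.0	11.0	8.3	8.1	12.3
LYS	lys14	-177.9	181.6	180.5	180.8	11.4	12.9	10.5	12.1
LYS	lys15	-179.3	182.0	-70.4	178.8	8.1	12.8	9.9	11.5
LYS	lys16	-177.2	-69.2	69.4	178.2	8.5	11.1	9.4	9.7
LYS	lys17	-178.6	-67.4	181.4	182.3	8.3	9.4	9.9	13.0
LYS	lys18	-179.6	-66.5	-69.1	182.9	8.2	11.9	8.4	10.7
LYS	lys19	-67.0	67.4	65.2	178.9	8.5	10.8	10.6	11.7
LYS	lys20	-69.0	70.0	179.6	178.4	11.6	10.0	8.6	11.8
LYS	lys21	-68.5	65.1	-66.8	179.7	12.8	8.6	9.9	10.8
LYS	lys22	-68.6	179.5	70.1	178.2	9.8	8.2	9.7	9.4
LYS	lys23	-69.9	182.6	177.6	179.7	8.3	10.1	11.9	8.2
LYS	lys24	-67.3	178.4	-68.2	177.6	9.0	11.5	8.1	9.3
LYS	lys25	-68.7	-70.1	70.1	178.9	12.0	12.9	11.1	10.0
LYS	lys26	-64.6	-65.6	177.3	181.0	11.0	9.7	12.2	8.2
LYS	lys27	-67.6	-70.1	-65.2	178.6	8.8	12.5	11.9	8.4
MET	met01	59.0	65.7	182.1		8.9	11.0	9.1	
MET	met02	59.2	178.3	182.0		12.3	9.3	8.5	
MET	met03	64.9	-62.9	178.2		8.3	10.9	9.3	
MET	met04	-180.0	66.9	179.4		9.9	11.1	10.9	
MET	met05	-175.6	180.1	179.5		8.1	9.9	10.0	
MET	met06	-176.6	-64.9	182.5		12.7	12.7	12.2	
MET	met07	-66.9	63.4	180.4		8.1	9.1	8.1	
MET	met08	-69.4	178.9	181.8		12.8	12.5	8.1	
MET	met09	-65.8	-64.5	182.3		12.3	10.4	8.7	
MET	met10	-175.4	-62.5	76.9		9.8	12.5	10.6	
MET	met11	-66.9	62.8	-72.7		9.1	10.2	12.9	
MET	met12	63.8	-68.0	-73.7		10.5	10.3	12.3	
MET	met13	60.5	67.9	-74.8		12.0	8.9	9.4	
GLU	glu01	59.5	65.1	-17.9		8.6	10.3	11.4	
GLU	glu02	60.5	179.2	-6.5		10.2	9.7	11.6	
GLU	glu03	-179.3	64.1	-12.3		10.3	9.0	11.8	
GLU	glu04	-176.4	177.8	-17.6		11.8	9.5	9.9	
GLU	glu05	-65.6	65.8	-9.6		10.8	12.1	9.1	
GLU	glu06	-65.7	178.0	-7.6		8.1	11.1	9.6	
GLU	glu07	-68.6	-68.0	-39.9		9.7	12.0	10.5	
GLU	glu08	-179.6	-64.6	18.7		9.9	9.0	8.8	
GLN	gln01	64.9	64.3	62.6		8.3	9.5	8.9	
GLN	gln02	59.4	182.4	-54.2		8.4	12.6	12.1	
GLN	gln03	60.2	-66.2	2.5		11.3	9.3	10.7	
GLN	gln04	-176.8	65.1	57.8		10.4	12.5	10.6	
GLN	gln05	-176.3	178.5	-54.5		10.7	10.6	11.5	
GLN	gln06	-174.1	-67.1	53.7		8.7	9.9	9.6	
GLN	gln07	-64.5	63.7	-5.9		9.5	10.1	8.9	
GLN	gln08	-67.1	178.8	56.4		10.6	9.6	11.8	
GLN	gln09	-68.9	-66.4	2.4		8.2	8.9	10.9	
ASP	asp01	60.2	-14.1			8.9	9.7		
ASP	asp02	-174.9	-18.0			10.3	10.2		
ASP	asp03	-64.3	-21.3			11.8	8.1		
ASP	asp04	-178.9	63.7			11.8	8.1		
ASP	asp05	-67.3	-48.8			12.1	11.8		
ASN	asn01	64.7	-25.9			9.5	12.4		
ASN	asn02	-177.8	-24.5			12.7	12.0		
ASN	asn03	-69.6	-16.9			10.8	8.1		
ASN	asn04	64.9	-74.8			12.5	10.3		
ASN	asn05	-175.9	61.0			12.0	9.3		
ASN	asn06	-64.8	119.4			9.1	9.8		
ASN	asn07	-65.2	-72.9			10.3	11.9		
ILE	ile01	60.5	101.8			11.6	8.2		
ILE	ile02	61.4	170.9			10.0	13.0		
ILE	ile03	-177.3	64.4			9.8	12.6		
ILE	ile04	-175.1	162.7			12.7	8.1		
ILE	ile05	-64.1	101.6			8.8	12.6		
ILE	ile06	-65.5	169.0			12.3	9.5		
ILE	ile07	-56.4	-58.0			9.2	9.3		
LEU	leu01	64.6	82.5			9.1	10.4		
LEU	leu02	-177.3	64.3			10.2	10.5		
LEU	leu03	-171.9	145.8			8.9	12.1		
LEU	leu04	-87.7	64.4			9.6	8.4		
LEU	leu05	-66.6	173.5			8.1	11.1		
HIS	his01	63.1	-77.8			10.1	11.2		
HIS	his02	64.6	80.3			8.4	10.7		
HIS	his03	-175.5	-75.9			12.0	8.0		
HIS	his04	-175.4	79.2			13.0	11.3		
HIS	his05	-67.7	-77.0			8.8	10.8		
HIS	his06	-65.1	77.9			9.4	8.3		
HIS	his07	-178.9	164.3			12.6	11.4		
HIS	his08	-66.0	165.0			9.9	8.2		
TRP	trp01	62.8	-87.0			10.1	9.8		
TRP	trp02	64.5	92.7			9.5	9.6		
TRP	trp03	-174.6	-107.9			9.4	12.4		
TRP	trp04	-179.8	90.0			8.5	10.6		
TRP	trp05	-69.6	-91.2			11.0	8.0		
TRP	trp06	-66.8	94.9			8.9	9.1		
TRP	trp07	-68.9	-6.2			11.8	12.0		
TYR	tyr01	59.3	91.5			12.0	10.7		
TYR	tyr02	-176.5	80.5			10.5	8.8		
TYR	tyr03	-178.7	-85.0			8.7	12.3		
TYR	tyr04	-65.7	-83.2			9.2	11.4		
TYR	tyr05	-67.6	-32.1			9.7	8.6		
TYR	tyr06	63.2	-87.8			8.5	9.1		
TYR	tyr07	-174.2	10.4			10.4	11.5		
PHE	phe01	59.4	87.4			8.9	8.5		
PHE	phe02	-179.0	77.4			9.4	8.8		
PHE	phe03	-63.7	-86.5			8.0	11.2		
PHE	phe04	-64.2	-29.7			11.4	11.5		
PRO	pro01	28.0	-30.0			7.0	7.0		
PRO	pro02	-28.0	30.0			7.0	7.0		
THR	thr01	61.1				8.0			
THR	thr02	-178.4				11.5			
THR	thr03	-68.9				10.7			
VAL	val01	64.8				12.6			
VAL	val02	-174.3				10.5			
VAL	val03	-64.7				10.9			
SER	ser01	61.9				9.8			
SER	ser02	-174.4				10.4			
SER	ser03	-67.5				10.3			
CYS	cys01	64.5				8.9			
CYS	cys02	-176.3				8.0			
CYS	cys03	-65.5				8.4			
ALA	ala01								
GLY	gly01								
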