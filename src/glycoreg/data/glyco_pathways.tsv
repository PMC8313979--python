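gene	pathway
UGCG	Glycolipid core
UGT8	Glycolipid core
B4GALT3	Glycolipid core
B4GALT4	Glycolipid core
B4GALT5	Glycolipid core
B4GALT6	Glycolipid core
GAL3ST1	Glycolipid core
ST3GAL5	Glycolipid core
A4GALT	P1-Pk blood group
B3GALNT1	P1-Pk blood group
B3GNT5	P1-Pk blood group
B4GALT1	P1-Pk blood group
UGCG	Gangliosides
ST3GAL5	Gangliosides
B4GALNT1	Gangliosides
ST8SIA1	Gangliosides
ST8SIA3	Gangliosides
ST8SIA5	Gangliosides
ST6GALNAC3	Gangliosides
ST6GALNAC4	Gangliosides
ST6GALNAC5	Gangliosides
ST6GALNAC6	Gangliosides
DPAGT1	Dolichol pathway
ALG1	Dolichol pathway
ALG2	Dolichol pathway
ALG3	Dolichol pathway
ALG5	Dolichol pathway
ALG6	Dolichol pathway
ALG8	Dolichol pathway
ALG9	Dolichol pathway
ALG10	Dolichol pathway
ALG11	Dolichol pathway
ALG12	Dolichol pathway
ALG13	Dolichol pathway
ALG14	Dolichol pathway
DDOST	Dolichol pathway
RPN1	Dolichol pathway
RPN2	Dolichol pathway
STT3A	Dolichol pathway
STT3B	Dolichol pathway
MOGS	Complex N-glycans
GANAB	Complex N-glycans
PRKCSH	Complex N-glycans
MAN1A1	Complex N-glycans
MAN1A2	Complex N-glycans
MAN1B1	Complex N-glycans
MAN2A1	Complex N-glycans
MAN2A2	Complex N-glycans
GNPTAB	Complex N-glycans
GNPTG	Complex N-glycans
NAGPA	Complex N-glycans
MGAT1	N-glycan branching
MGAT2	N-glycan branching
MGAT3	N-glycan branching
MGAT4A	N-glycan branching
MGAT4B	N-glycan branching
MGAT5	N-glycan branching
GALNT1	GalNAc-type O-glycans
GALNT2	GalNAc-type O-glycans
GALNT3	GalNAc-type O-glycans
GALNT4	GalNAc-type O-glycans
GALNT5	GalNAc-type O-glycans
GALNT6	GalNAc-type O-glycans
C1GALT1	GalNAc-type O-glycans
C1GALT1C1	GalNAc-type O-glycans
GCNT1	GalNAc-type O-glycans
B3GNT6	GalNAc-type O-glycans
GCNT3	GalNAc-type O-glycans
XYLT1	CS-HS initiation
XYLT2	CS-HS initiation
B4GALT7	CS-HS initiation
B3GALT6	CS-HS initiation
B3GAT3	CS-HS initiation
FAM20B	CS-HS initiation
CSGALNACT1	CS-HS initiation
CSGALNACT2	CS-HS initiation
EXTL3	CS-HS initiation
CSGALNACT1	CS-DS extension
CSGALNACT2	CS-DS extension
CHSY1	CS-DS extension
CHSY3	CS-DS extension
CHPF	CS-DS extension
CHPF2	CS-DS extension
CHST3	CS-DS extension
CHST11	CS-DS extension
CHST12	CS-DS extension
CHST13	CS-DS extension
UST	CS-DS extension
DSE	CS-DS extension
DSEL	CS-DS extension
EXT1	Heparan sulfate extension
EXT2	Heparan sulfate extension
EXTL1	Heparan sulfate extension
EXTL2	Heparan sulfate extension
EXTL3	Heparan sulfate extension
HS2ST1	Heparan sulfate extension
HS3ST1	Heparan sulfate extension
HS6ST1	Heparan sulfate extension
GLCE	Heparan sulfate extension
NDST1	Heparan sulfate extension
NDST2	Heparan sulfate extension
HAS1	Hyaluronan synthesis
HAS2	Hyaluronan synthesis
HAS3	Hyaluronan synthesis
PIGA	GPI anchor synthesis
PIGB	GPI anchor synthesis
PIGM	GPI anchor synthesis
PIGV	GPI anchor synthesis
PIGZ	GPI anchor synthesis
GPAA1	GPI anchor synthesis
POMT1	O-Mannose
POMT2	O-Mannose
POMGNT1	O-Mannose
POMGNT2	O-Mannose
MGAT5B	O-Mannose
B3GALNT2	O-Mannose
POFUT1	O-linked fucose
MFNG	O-linked fucose
LFNG	O-linked fucose
RFNG	O-linked fucose
B3GNT2	Type 1 and 2 LacNAc
B3GNT3	Type 1 and 2 LacNAc
B4GALT1	Type 1 and 2 LacNAc
B4GALT2	Type 1 and 2 LacNAc
B4GALT3	Type 1 and 2 LacNAc
B4GALT4	Type 1 and 2 LacNAc
GCNT1	Type 1 and 2 LacNAc
GCNT2	Type 1 and 2 LacNAc
GCNT3	Type 1 and 2 LacNAc
ST3GAL1	Sialylation
ST3GAL2	Sialylation
ST3GAL3	Sialylation
ST3GAL4	Sialylation
ST3GAL5	Sialylation
ST3GAL6	Sialylation
ST6GAL1	Sialylation
ST6GAL2	Sialylation
ST6GALNAC1	Sialylation
ST6GALNAC2	Sialylation
ST6GALNAC3	Sialylation
ST6GALNAC4	Sialylation
ST6GALNAC5	Sialylation
ST6GALNAC6	Sialylation
ST8SIA1	Sialylation
ST8SIA2	Sialylation
ST8SIA3	Sialylation
ST8SIA4	Sialylation
ST8SIA5	Sialylation
ST8SIA6	Sialylation
FUT1	Fucosylation
FUT2	Fucosylation
FUT3	Fucosylation
FUT4	Fucosylation
FUT5	Fucosylation
FUT6	Fucosylation
FUT7	Fucosylation
FUT9	Fucosylation
ABO	ABO blood group
FUT1	ABO blood group
FUT2	ABO blood group
B4GALNT3	LacDiNAc
B4GALNT4	LacDiNAc
GAL3ST1	Sulfated glycan epitopes
CHST1	Sulfated glycan epitopes
CHST2	Sulfated glycan epitopes
CHST4	Sulfated glycan epitopes
CHST8	Sulfated glycan epitopes
CHST9	Sulfated glycan epitopes
CHST10	Sulfated glycan epitopes
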