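# Curated plant cis-regulatory element consensus sequences (IUPAC).
# A small default library; full-scale collections (PLACE, RegSite) can be
# loaded from any TSV with the same two columns.
name	consensus
G-box	CACGTG
G-box-extended	MCACGTGK
ABRE	ACGTGKC
ABRE-like	BACGTGKM
as-1/ocs	TGACG
Hex-motif	TGACGTGG
W-box	TTGACY
GCC-box	GCCGCC
DRE/CRT	RCCGAC
LTRE-core	CCGAC
I-box	GATAAG
GT-1-site	GRWAAW
GATA-motif	WGATAR
AuxRE	TGTCTC
E-box	CANNTG
MYB-core	CNGTTR
MYB-P-box	CCWACC
CAAT-box	CCAAT
TATA-box	TATAWAW
Telo-box	AAACCCTA
SiteII-motif	TGGGCY
ARR1-motif	NGATT
DOF-core	AAAG
CArG-box	CCWWWWWWGG
Pyrimidine-box	CCTTTT
GARE	TAACAAR
RY-element	CATGCA
Evening-element	AAAATATCT
Prolamin-box	TGYAAAG
SEF4-motif	RTTTTTR
SORLIP1	GCCAC
CCA1-binding	AAMAATCT
AT1-box	AATATTTTTATT
GAGA-element	GAGAGAGA
TCP-site	GGNCCCAC
WUN-motif	AAATTTCCT
O2-site	GATGAYRTGR
P-box	CCTTTTG
AACA-motif	AACAAAC
TGA-element	AACGAC
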