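# Quality-trait dictionary used across the pooled GWAS studies. Codes may repeat
# with distinct descriptions; every (code, description) pair is one entry.
code	description
a*	Redness
AX	Arabinoxylan
b*	Yellowness
BG	Beta-glucan
CLOSS	Cooking loss
Color	Color a, b, or L
Color	Pasta color
CWT	Cooked weight
DEE	Deformation energy
dif	Difference in color a, b or L
DOE	Dough extensibility
DOTE	Dough tenacity
Fb	Flour yellow color
FIRM	Firmness
GCaC	Grain calcium content
GCdC	Grain cadmium content
GCuC	Grain copper content
GFeC	Grain iron content
GKC	Grain potassium content
GL	Grain length
Gli	Gliadins
Glu	Glutenins
GLUT	Glutork
GMgC	Grain magnesium content
GMnC	Grain manganese content
GPC	Grain protein content
GPC	Protein content
GS	Gluten index
GS	Gluten strength
GSC	Grain sulfur content
GSeC	Grain selenium content
GseY	Grain selenium yield
GW	Grain width
GZnC	Grain zinc content
HMW	High molecular weight GS
IP	Immunogenic gluten epitopes
L*	Brightness
LMW	Low molecular weight GS
MIXO	Mixogram score
PGC	Phosphorus grain content
PLOSS	Pigment loss
PPO	Polyphenol oxidase activity
PRLOSS	Protein loss
SASH	Semolina ash
SEXT	Semolina extraction
SPROT	Semolina protein
SV	SDS-sedimentation volume
TEXT	Total extraction
TPT	Toxic peptides
TW	Test weight
VIT	Kernel vitreouness
WG	Wet gluten
WTS	Work to shear
YPC	Pasta b*
YPC	Semolina b*
YPC	Semolina pigment
YPC	Yellow pigment content
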