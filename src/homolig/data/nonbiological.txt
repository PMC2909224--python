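# Common non-biological small molecules found in crystal structures:
# buffers, cryoprotectants, detergents, precipitants and purification
# additives, by PDB chemical component code.  One code per line.
# Replace with your own list to change the exclusion policy.

# cryoprotectants / polyols
GOL     # glycerol
EDO     # ethylene glycol
PGO     # propylene glycol
MPD     # 2-methyl-2,4-pentanediol
MRD     # (4R)-2-methylpentane-2,4-diol
PEG     # di(hydroxyethyl)ether
PG4     # tetraethylene glycol
PGE     # triethylene glycol
1PE     # pentaethylene glycol
2PE     # nonaethylene glycol
P6G     # hexaethylene glycol
SUC     # sucrose (cryoprotectant use)

# buffers
MES     # 2-(N-morpholino)ethanesulfonic acid
EPE     # HEPES
TRS     # TRIS
BTB     # bis-tris buffer
IMD     # imidazole
CAC     # cacodylate
PIN     # PIPES

# salts / precipitants / small acids
ACT     # acetate
ACY     # acetic acid
FMT     # formate
CIT     # citric acid
FLC     # citrate anion
TLA     # L-tartaric acid
MLI     # malonate
SO4     # sulfate
PO4     # phosphate
NO3     # nitrate
CO3     # carbonate
BCT     # bicarbonate
AZI     # azide

# reducing agents / solvents / detergents
BME     # beta-mercaptoethanol
DTT     # dithiothreitol
DMS     # dimethyl sulfoxide
EOH     # ethanol
MOH     # methanol
IPA     # isopropyl alcohol
ACN     # acetone
BOG     # octyl beta-D-glucopyranoside
LDA     # lauryl dimethylamine-N-oxide
SDS     # dodecyl sulfate
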