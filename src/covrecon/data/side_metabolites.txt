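# Default currency/side metabolites excluded from pathway search.
# One compartment-stripped base id per line; edit or replace freely.
# KEGG compound ids for the same species are listed alongside.
h2o
h
o2
co2
nh4
pi
ppi
atp
adp
amp
nad
nadh
nadp
nadph
coa
q8
q8h2
fad
fadh2
h2o2
so4
cl
k
na1
fe2
fe3
C00001
C00080
C00007
C00011
C00014
C00009
C00013
C00002
C00008
C00020
C00003
C00004
C00006
C00005
C00010
C00016
C01352
C00027
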