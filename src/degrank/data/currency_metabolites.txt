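# Currency / highly connected metabolites removed before pathway-distance
# calculations, matched per compartment by metabolite name or by id with the
# compartment suffix stripped.  This is the package's default stand-in for a
# curated highly-connected-metabolite table; pass an explicit list to replace
# it (degrank.distance.PruneSpec.explicit).
atp
adp
amp
gtp
gdp
gmp
utp
udp
ump
ctp
cdp
cmp
nad
nadh
nad(+)
nad+
nadp
nadph
nadp(+)
nadp+
coenzyme a
coa
acetyl-coa
h2o
water
h
h+
proton
pi
phosphate
ppi
diphosphate
co2
carbon dioxide
o2
oxygen
nh4
ammonium
fad
fadh2
s-adenosyl-l-methionine
s-adenosyl-l-homocysteine
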