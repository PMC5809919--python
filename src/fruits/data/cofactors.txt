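# Cofactors excluded from side-product candidacy: energy carriers and
# redox equivalents whose co-production does not represent a tappable
# anabolic by-product.  One id per line, matched case-insensitively
# against metabolite ids with and without their compartment suffix
# (BiGG-style base ids).  Edit or replace via the --cofactors option.
#
# Free CoA is excluded as a carrier; acyl thioesters (e.g. acetyl-CoA)
# are deliberately NOT listed — they are trimmed or kept on their own
# merits.
atp
adp
amp
nad
nadh
nadp
nadph
coa
fad
fadh2
gtp
gdp
gmp
utp
udp
ump
ctp
cdp
cmp
q8
q8h2
mqn8
mql8
pq
pqh2
h2o
h
co2
pi
ppi
o2
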