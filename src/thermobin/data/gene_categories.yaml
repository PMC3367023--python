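# Default biogeochemical gene-category map.
#
# Sulfur cycle: dsr/apr/sat act in both sulfide oxidation and sulfate
# reduction; they are counted under sulfate_reduction only and deliberately
# excluded from sulfide_oxidation so the two tallies stay disjoint.
sulfate_reduction: [dsr, apr, sat]
sulfide_oxidation: [sor, apat, soxA, soxB, soxC, soxD, soxX, soxY, soxZ, tqr, sqr, fcsd]
denitrification: [nar, nir, nor, nos]
nitrogen_fixation: [nif]
nitrification: [hao, amo]
# Carbon fixation pathway proxies: citryl-CoA synthase/lyase and pyruvate
# ferredoxin oxidoreductase for the reverse TCA cycle; RuBisCO for the
# Calvin cycle; CO dehydrogenase for the reductive acetyl-CoA pathway;
# malonate semialdehyde reductase for 3-hydroxypropionate; and
# 4-hydroxybutyryl-CoA dehydratase for 3-hydroxypropionate/4-hydroxybutyrate.
rTCA: [ccsA, cclA, oorA, oorB, oorC, oorD]
CBB: [rbcL]
rACP: [cooS]
3HP: [msr]
3-4HP: [abfD]
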