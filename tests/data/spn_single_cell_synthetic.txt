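# SYNTHETIC reconstruction of the Drosophila melanogaster single-cell
# segment-polarity Boolean network (n = 17), rebuilt from the published
# segment-polarity logic (Albert & Othmer lineage) with the neighbor
# signals collapsed to the two inputs nWG and nHH; it is a stand-in for
# the published rule file, which is not bundled here.
# Inputs (self-copies, usually pinned): SLP, nWG, nHH.
SLP* = SLP
nWG* = nWG
nHH* = nHH
wg* = (CIA and SLP and not CIR) or (wg and (CIA or SLP) and not CIR)
WG* = wg
en* = nWG and not SLP
EN* = en
hh* = EN and not CIR
HH* = hh
ptc* = CIA and not EN and not CIR
PTC* = ptc or (PTC and not nHH)
PH* = PTC and nHH
SMO* = not PTC or nHH
ci* = not EN
CI* = ci
CIA* = CI and (SMO or nHH)
CIR* = CI and not SMO and not nHH
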