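# Default wild-type parameter set at 22 degC, with 27 degC overrides.
#
# These values are calibrated within this repository (see docs/methods.md):
# base rates were chosen on physiological scales (hours, arbitrary
# concentration units) and the growth/PIF4-subsystem parameters were fitted
# with pif4net.fitting against the packaged wild-type hypocotyl anchors at
# day lengths 4/8/12/16 h.  They are NOT published values.
pB: 2.0
kr: 0.19
pE1: 1.0
pE2: 0.8
alpha: 2.0
dEC: 0.5
dE: 0.3
pCL: 0.3
pCD: 1.2
dC: 0.5
pP: 5.0
pPE: 1.0
pself: 8.0
dP: 3.0
kPC: 3.0
dPB: 7.0
Pstar: 0.6
k0: 0.05
pF: 2.0
pFP: 3.0
dF: 0.4
pG: 0.0043
kG: 0.169
pGP: 1.0
pGE: 0.3
pGB: 8.0
temperature_variants:
  "22": {}
  "27":
    pB: 1.6
    kr: 0.35
    pE1: 1.0
    pE2: 0.7
    pPE: 0.8
    pCL: 0.3
    k0: 0.06
    Pstar: 0.75
    pself: 6.0
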