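# Genotype registry: multiplicative production factors and per-genotype
# overrides of the autoinhibition threshold/strength.  Magnitudes are
# repo-calibrated to reproduce the qualitative reporter and hypocotyl
# panels (see docs/methods.md); they are not published values.
WT: {}
pif4-101:
  mutP: 0.05
  overrides:
    Pstar: 0.01
PIF4-OE1:
  mutP: 2.5
PIF4-OE2:
  mutP: 5.0
PIF4-OE3:
  mutP: 8.0
cop1-4:
  mutC: 0.1
cop1-6:
  mutC: 0.15
det1-1:
  mutC: 0.12
35S:COP1:
  mutC: 3.0
phyb-9:
  mutB: 0.05
35S:PHYB:
  mutB: 2.0
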