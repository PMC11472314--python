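# Effective one-lipid component volumes (A^3) and electron counts for the
# lipid model membranes, composition-weighted over each mixture.  Values are
# rounded literature-style estimates for fluid-phase lipids at 37 C and set
# the default generating conditions; analyses of real data should substitute
# measured volumes.
#
# gneg_im : POPE/POPG/TOCL 7:2:1      (Gram-negative inner membrane mimic)
# gpos    : POPG/DOTAP/POPE/TOCL 6:1.5:1.5:1  (Gram-positive mimic)
# euk33   : SOPC/PLPC/POPE/ESM/chol   (eukaryotic mimic, 33 mol% cholesterol)
gneg_im:
  phos: {volume: 180.0, electrons: 90.0}
  cg: {volume: 147.0, electrons: 67.0}
  ch2: {volume: 920.0, electrons: 264.0}
  ch3: {volume: 110.0, electrons: 18.0}
  water: {volume: 30.0, electrons: 10.0}
gpos:
  phos: {volume: 185.0, electrons: 92.0}
  cg: {volume: 147.0, electrons: 67.0}
  ch2: {volume: 940.0, electrons: 270.0}
  ch3: {volume: 110.0, electrons: 18.0}
  water: {volume: 30.0, electrons: 10.0}
euk33:
  phos: {volume: 210.0, electrons: 102.0}
  cg: {volume: 140.0, electrons: 64.0}
  ch2: {volume: 960.0, electrons: 278.0}
  ch3: {volume: 100.0, electrons: 17.0}
  water: {volume: 30.0, electrons: 10.0}
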