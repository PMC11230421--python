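# Default per-species centromere features for the 17-taxon
# Euarchontoglires panel.
#
# hor: species whose centromere satellites show higher-order repeat (HOR)
#   structure.
# cenpb_high: species with a high abundance of functional CENP-B box
#   motifs in their centromere satellite (Mus shrew mouse is grouped with
#   the CENP-B-absent species: only one of its chromosomes carries a high
#   density of CENP-B repeats).
# clades: coarse clade membership used for the rodents/primates regimes.

hor:
  - rat
  - human
  - bonobo
  - chimpanzee
  - orangutan
  - mouse_lemur

cenpb_high:
  - marmoset
  - human
  - bonobo
  - chimpanzee
  - gorilla
  - orangutan
  - house_mouse
  - algerian_mouse

clades:
  human: primate
  chimpanzee: primate
  bonobo: primate
  gorilla: primate
  orangutan: primate
  macaque: primate
  marmoset: primate
  mouse_lemur: primate
  house_mouse: rodent
  steppe_mouse: rodent
  algerian_mouse: rodent
  ryukyu_mouse: rodent
  shrew_mouse: rodent
  rat: rodent
  chinese_hamster: rodent
  naked_mole_rat: rodent
  rabbit: lagomorph
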