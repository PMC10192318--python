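# Required-domain sets used to assign a protein to an actor category from
# per-sequence domain hits. A protein joins a category when ALL domains in
# `required` are present (matched against domain name or accession).
# `flags` map a flag name to an extra domain set that, when also present,
# annotates the entry (e.g. CARD-bearing initiator caspases, "classical"
# calpains carrying both peptidase domains and an EF-hand).
caspase:
  required: [Caspase_P20]
  flags:
    initiator_card: [CARD]
    initiator_ded: [DED]
bcl2_multidomain:
  required: [Bcl-2]
  flags:
    bh4: [BH4]
bh3_only:
  required: [BH3]
  flags: {}
death_receptor:
  required: [TNFR_c6, Death]
  flags: {}
adaptor_protein:
  required: [Death, DED]
  flags: {}
iap:
  required: [BIR]
  flags: {}
apaf1:
  required: [NB-ARC, WD40]
  flags:
    card_apaf: [CARD]
p53:
  required: [P53_DNA-bd]
  flags: {}
cytochrome_c:
  required: [Cytochrom_C]
  flags: {}
calpain:
  required: [Peptidase_C2]
  flags:
    classical: [Calpain_III, EF-hand]
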