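# Default guide-RNA configuration.
#
# miR390 mature #1 is the deeply conserved land-plant 21-mer; the second
# mature variant and the star variant are synthetic stand-ins constructed to
# exercise the variant-set semantics (a scan hit may match ANY variant) and
# the canonical duplex geometry. Swap in curated miRBase entries for real
# screens. miR156/miR529 are the conserved family sequences used for TAS6
# dual-site detection.
guides:
  miR390:
    mature:
      - AAGCUCAGGAGGGAUAGCGCC
      - AAGCUCAGGAGGGAUAGCACC
    star:
      - CGCUAUCCCUCCUGAGCUUCU
  miR156:
    mature:
      - UGACAGAAGAGAGUGAGCAC
    star: []
  miR529:
    mature:
      - AGAAGAGAGAGAGUACAGCUU
    star: []
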