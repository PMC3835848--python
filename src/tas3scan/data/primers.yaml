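# Default degenerate primer sets for in-silico PCR profiling.
#
# TAS-dicot is the published dicot TAS3 set: forward TAS-P with the
# TAS-Mcaa/TAS-Maca reverse mixture. The miR390-precursor primer pair
# (P-mir/M-mir) and the bryophyte TAS set (BryoTAS-P/M) have no published
# sequences; configure them per project.
primer_sets:
  - name: TAS-dicot
    forward: GGTGCTATCCTATCTGAGCTT
    reverse:
      - AGCTCAGGAGGGATAGCAA
      - AGCTCAGGAGGGATAGACA
    max_mm: 2
    three_prime_exact: 3
    product_range: [80, 1500]
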