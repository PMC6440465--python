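# Default cis-acting element catalog (IUPAC consensus strings).
# Consensus strings for several of these elements vary between motif-database
# versions; replace this file with a database export for production scans.
elements:
  - name: G-Box
    patterns: [CACGTG]
    class: light
  - name: ABRE
    patterns: [TACGTGTC]
    class: hormone-ABA
  - name: CGTCA-motif
    patterns: [CGTCA]
    class: hormone-MeJA
  - name: TGACG-motif
    patterns: [TGACG]
    class: hormone-MeJA
  - name: P-box
    patterns: [CCTTTTG]
    class: hormone-GA
  - name: GARE-motif
    patterns: [TCTGTTG]
    class: hormone-GA
  - name: TGA-element
    patterns: [AACGAC]
    class: hormone-auxin
  - name: TCA-element
    patterns: [CCATCTTTTT]
    class: hormone-SA
  - name: HSE
    patterns: [AAAAAATTTC]
    class: stress
  - name: MBS
    patterns: [CAACTG]
    class: stress
  - name: TC-rich repeats
    patterns: [ATTTTCTTCA]
    class: stress
  - name: CAT-box
    patterns: [GCCACT]
    class: meristem
  - name: CCGTCC-box
    patterns: [CCGTCC]
    class: meristem
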