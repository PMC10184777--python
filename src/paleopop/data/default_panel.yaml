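# Default appearance panel: the classic canine coat/eye loci named in the
# main coat-color literature, with approximate CanFam3.1 coordinates.
# Genotypes count ALT (variant) alleles; users with a complete variant
# panel supply their own file in the same schema.
loci:
  - locus: k_locus            # CBD103 dominant black
    channel: base color
    site: [chr16, 58965448, G, A]
    genotype_map:
      "0": agouti-determined color
      "1": black (dominant)
      "2": black (dominant)
      missing: unknown
    masked_by: []

  - locus: tan_points         # ASIP a^t
    channel: pattern
    site: [chr24, 23393510, C, T]
    genotype_map:
      "0": no tan points
      "1": no tan points      # a^t is recessive
      "2": tan points
      missing: unknown
    masked_by:
      - [em_mask, melanistic mask]

  - locus: wolf_agouti        # ASIP aw
    channel: pattern
    site: [chr24, 23355900, G, A]
    genotype_map:
      "0": no wolf agouti
      "1": wolf agouti
      "2": wolf agouti
      missing: unknown
    masked_by: []

  - locus: domino             # MC1R Northern domino
    channel: pattern
    site: [chr5, 63694334, C, T]
    genotype_map:
      "0": no domino
      "1": no domino
      "2": domino
      missing: unknown
    masked_by: []

  - locus: em_mask            # MC1R E^M melanistic mask
    channel: mask
    site: [chr5, 63694460, C, T]
    genotype_map:
      "0": no mask
      "1": melanistic mask
      "2": melanistic mask
      missing: unknown
    masked_by: []

  - locus: blue_eyes          # ALX4 duplication-linked variant
    channel: eye color
    site: [chr18, 44924848, A, G]
    genotype_map:
      "0": brown eyes
      "1": blue eyes
      "2": blue eyes
      missing: unknown
    masked_by:
      - [em_mask, melanistic mask]

  - locus: white_spotting     # MITF-M promoter region; call supplied upstream
    channel: white spotting
    region: [chr20, 21836232, 21839366]
    genotype_map:
      "0": minimal white
      "1": some white
      "2": extensive white
      missing: unknown
    masked_by: []

  - locus: coat_layer         # chr28 cis-regulatory single-coat allele
    channel: coat layer
    site: [chr28, 23966159, T, C]
    genotype_map:
      "0": double-layered coat
      "1": double-layered coat
      "2": single-layered coat
      missing: unknown
    masked_by: []

  - locus: pigment_intensity  # MFSD12 dilution of phaeomelanin
    channel: pigment intensity
    site: [chr20, 55850145, G, A]
    genotype_map:
      "0": deep red pigment
      "1": intermediate pigment
      "2": light tan pigment
      missing: unknown
    masked_by: []
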