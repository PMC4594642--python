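# Chromosomal stasis regime: essentially no fixed rearrangements per myr,
# matching the long quiet branches seen in painted phyllostomid lineages.
root_chromosomes = 18
blocks_per_chromosome = 2
fusion_rate = 0.01
fission_rate = 0.01
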