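# Megaevolution burst regime: ~6 fixed events/myr, the upper extreme of
# observed branch rates (dozens of fusions/fissions over a few myr).
root_chromosomes = 18
blocks_per_chromosome = 2
fusion_rate = 4.0
fission_rate = 2.0
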