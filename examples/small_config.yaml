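# Small end-to-end pipeline configuration: 3 ingroup + 1 outgroup
# transcriptomes, 20 loci with the default injection mix, 2,000 reads.
simulate:
  n_loci: 20
  n_reads: 2000
  read_len: 150
  on_target_fraction: 0.5
select:
  focal_species: [AloeA, AloeB, AloeC]
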