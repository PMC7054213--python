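# Example end-to-end pipeline config for `sigtool pipeline`.
# A toy genome and VCF are simulated, catalogued and factorised.
seed: 11
stages:
  simulate:
    genome_length: 20000
    n_sbs: 60
    n_dbs: 20
    n_indels: 40
  catalogue:
    schema: SBS96
  extract:
    kmin: 1
    kmax: 3
    iterations: 32
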