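# 105-day egg survey of a 48-female (male-free) habitat.
n_females: 48
monitoring_days: 105
n_eggs: 1053           # non-wind egg cases monitored
n_fertile: 28          # eggs that developed an embryo
n_hatched: 5           # all five hatchlings genotyped
n_embryos_genotyped: 9
n_embryos_parthenote: 7
n_ungenotyped_fertile: 14
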