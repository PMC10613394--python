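name,total_cost,dmft_averted
do_nothing,0,0
apf_gel,54024439,42010
sugar_reduction,91380,63762
tooth_brushing,72779917,74018
fissure_sealant,44633687,100024
art,45057166,144035
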