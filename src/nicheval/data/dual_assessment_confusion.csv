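expert1_category,expert2_category,count
excellent,excellent,2
good,excellent,2
moderate,excellent,1
poor,excellent,1
excellent,good,9
good,good,16
moderate,good,7
poor,good,5
excellent,moderate,9
good,moderate,39
moderate,moderate,44
poor,moderate,14
excellent,poor,1
good,poor,14
moderate,poor,62
poor,poor,64
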