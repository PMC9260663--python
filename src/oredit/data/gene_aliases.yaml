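# Normalisation map for inconsistent gene spellings in the transcribed
# summary-table fixture; counts of distinct edited genes reproduce only
# after applying it.
rsp2: rps2
rsp12: rps12
apt6: atp6
apt1: atp1
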