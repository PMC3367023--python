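site,reads,avg_read_length,total_bases
site1,74183,1111,82446031
site2,88801,889,78909662
site3,76401,1145,87473573
site4,134669,957,128927040
site5,100202,932,93352445
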