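label,D,A,Ht,Ha,percent_yield_reported,percent_ratio_reported,enrichment_reported,false_negatives_reported,false_positives_reported,gh_reported
Hypo I,796,37,121,28,23.15,75.68,4.98,9,93,0.32
Hypo II,796,37,60,30,50,81.1,10.78,7,30,0.56
Hypo III,796,37,45,35,77.78,94.6,16.74,2,10,0.81
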