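item_group,criterion,mean,sd
symptoms,accuracy,4.9,0.1
symptoms,simplicity,4.7,0.2
symptoms,usefulness,4.5,0
symptoms,adequacy,4.6,0.2
diseases,accuracy,4.9,0.2
diseases,simplicity,4.6,0.3
diseases,usefulness,4.4,0.1
diseases,adequacy,4,0.1
drugs,accuracy,4.8,0.1
drugs,simplicity,4.3,0.3
drugs,usefulness,4,0.1
drugs,adequacy,4.6,0.2
tests,accuracy,5,0
tests,simplicity,4.8,0.1
tests,usefulness,5,0
tests,adequacy,5,0
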