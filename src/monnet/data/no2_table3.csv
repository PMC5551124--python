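cluster,n_current,n_subject,n_candidate
1,2,228,5
2,0,2,0
3,0,2131,33
4,0,1577,20
5,21,20935,247
6,1,3336,32
7,1,187,4
8,12,2701,71
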