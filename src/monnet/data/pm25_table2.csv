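cluster,n_current,n_subject,n_candidate
1,9,2587,60
2,0,505,19
3,16,14888,131
4,0,34,0
5,1,187,4
6,3,303,7
7,0,2246,25
8,3,6780,136
9,5,3567,30
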