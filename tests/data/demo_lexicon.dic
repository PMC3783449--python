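%
1	affect
2	posemo
3	negemo
%
happ*	1 2
glad	1 2
sad	1 3
love	1 2
hate	1 3
ugh	3
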