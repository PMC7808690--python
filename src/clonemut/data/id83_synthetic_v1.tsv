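# synthetic stand-in indel signature catalog v1 (package-made test signatures, not published matrices)
channel	SYN_INS_SLIP	SYN_DEL_SLIP	SYN_DEL_MH
1:Del:C:0	0.000632911392	0.000632911392	0.000636942675
1:Del:C:1	0.000632911392	0.000632911392	0.000636942675
1:Del:C:2	0.000632911392	0.000632911392	0.000636942675
1:Del:C:3	0.000632911392	0.000632911392	0.000636942675
1:Del:C:4	0.000632911392	0.000632911392	0.000636942675
1:Del:C:5	0.000632911392	0.000632911392	0.000636942675
1:Del:T:0	0.000632911392	0.000632911392	0.000636942675
1:Del:T:1	0.000632911392	0.000632911392	0.000636942675
1:Del:T:2	0.000632911392	0.237500000032	0.000636942675
1:Del:T:3	0.000632911392	0.237500000000	0.000636942675
1:Del:T:4	0.000632911392	0.237500000000	0.000636942675
1:Del:T:5	0.000632911392	0.237500000000	0.000636942675
1:Ins:C:0	0.000632911392	0.000632911392	0.000636942675
1:Ins:C:1	0.000632911392	0.000632911392	0.000636942675
1:Ins:C:2	0.000632911392	0.000632911392	0.000636942675
1:Ins:C:3	0.000632911392	0.000632911392	0.000636942675
1:Ins:C:4	0.000632911392	0.000632911392	0.000636942675
1:Ins:C:5	0.000632911392	0.000632911392	0.000636942675
1:Ins:T:0	0.000632911392	0.000632911392	0.000636942675
1:Ins:T:1	0.000632911392	0.000632911392	0.000636942675
1:Ins:T:2	0.237500000032	0.000632911392	0.000636942675
1:Ins:T:3	0.237500000000	0.000632911392	0.000636942675
1:Ins:T:4	0.237500000000	0.000632911392	0.000636942675
1:Ins:T:5	0.237500000000	0.000632911392	0.000636942675
2:Del:R:0	0.000632911392	0.000632911392	0.000636942675
2:Del:R:1	0.000632911392	0.000632911392	0.000636942675
2:Del:R:2	0.000632911392	0.000632911392	0.000636942675
2:Del:R:3	0.000632911392	0.000632911392	0.000636942675
2:Del:R:4	0.000632911392	0.000632911392	0.000636942675
2:Del:R:5	0.000632911392	0.000632911392	0.000636942675
3:Del:R:0	0.000632911392	0.000632911392	0.000636942675
3:Del:R:1	0.000632911392	0.000632911392	0.000636942675
3:Del:R:2	0.000632911392	0.000632911392	0.000636942675
3:Del:R:3	0.000632911392	0.000632911392	0.000636942675
3:Del:R:4	0.000632911392	0.000632911392	0.000636942675
3:Del:R:5	0.000632911392	0.000632911392	0.000636942675
4:Del:R:0	0.000632911392	0.000632911392	0.135941765254
4:Del:R:1	0.000632911392	0.000632911392	0.000636942675
4:Del:R:2	0.000632911392	0.000632911392	0.000636942675
4:Del:R:3	0.000632911392	0.000632911392	0.000636942675
4:Del:R:4	0.000632911392	0.000632911392	0.000636942675
4:Del:R:5	0.000632911392	0.000632911392	0.000636942675
5:Del:R:0	0.000632911392	0.000632911392	0.135941765241
5:Del:R:1	0.000632911392	0.000632911392	0.000636942675
5:Del:R:2	0.000632911392	0.000632911392	0.000636942675
5:Del:R:3	0.000632911392	0.000632911392	0.000636942675
5:Del:R:4	0.000632911392	0.000632911392	0.000636942675
5:Del:R:5	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:0	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:1	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:2	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:3	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:4	0.000632911392	0.000632911392	0.000636942675
2:Ins:R:5	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:0	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:1	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:2	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:3	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:4	0.000632911392	0.000632911392	0.000636942675
3:Ins:R:5	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:0	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:1	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:2	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:3	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:4	0.000632911392	0.000632911392	0.000636942675
4:Ins:R:5	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:0	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:1	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:2	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:3	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:4	0.000632911392	0.000632911392	0.000636942675
5:Ins:R:5	0.000632911392	0.000632911392	0.000636942675
2:Del:M:1	0.000632911392	0.000632911392	0.000636942675
3:Del:M:1	0.000632911392	0.000632911392	0.000636942675
3:Del:M:2	0.000632911392	0.000632911392	0.000636942675
4:Del:M:1	0.000632911392	0.000632911392	0.000636942675
4:Del:M:2	0.000632911392	0.000632911392	0.000636942675
4:Del:M:3	0.000632911392	0.000632911392	0.000636942675
5:Del:M:1	0.000632911392	0.000632911392	0.135941765241
5:Del:M:2	0.000632911392	0.000632911392	0.135941765241
5:Del:M:3	0.000632911392	0.000632911392	0.135941765241
5:Del:M:4	0.000632911392	0.000632911392	0.135941765241
5:Del:M:5	0.000632911392	0.000632911392	0.135941765241
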