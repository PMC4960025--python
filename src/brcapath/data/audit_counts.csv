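pathway_id,count,basis
1,9,recorded
2,9,inferred_split
3,1,inferred_split
4,7,recorded
5,0,recorded
6,23,recorded
7,3,recorded
8,4,recorded
9,12,recorded
10,16,recorded
11,7,recorded
12,8,recorded
13,15,recorded
14,9,recorded
15,18,recorded
16,8,recorded
17,2,pending_rule
18,2,pending_rule
19,11,recorded
20,0,recorded
21,1,recorded
22,32,recorded
23,5,recorded
24,3,recorded
25,3,recorded
26,3,recorded
27,9,recorded
28,0,recorded
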