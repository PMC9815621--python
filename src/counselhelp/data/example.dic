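%
1	NegEmo
2	PosEmo
3	Anx
4	Sad
5	Insight
6	Preps
%
afraid	1,3
anxious	1,3
cry	1,4
down	1,4
glad	2
happi*	2
nervous	1,3
sad*	1,4
worr*	1,3
joy*	2
realiz*	5
understand	5
think*	5
about	6
with	6
from	6
into	6
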