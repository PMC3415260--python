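# Person-name trigger patterns: category<TAB>pattern<TAB>direction.
# direction says on which side of the pattern capitalized words are captured.
relation	my daughter	following
relation	my son	following
relation	my wife	following
relation	my husband	following
relation	my mother	following
relation	my father	following
relation	my brother	following
relation	my sister	following
relation	my aunt	following
relation	my uncle	following
relation	my cousin	following
relation	my grandmother	following
relation	my grandfather	following
relation	an uncle of	following
relation	an aunt of	following
relation	a cousin of	following
relation	the mother of	following
relation	the father of	following
self_id	my name is	following
self_id	my name	following
self_id	sincerely	following
self_id	regards	following
self_id	yours truly	following
self_id	signed	following
self_id	on behalf of	following
life_event	was born	preceding
life_event	born in	preceding
life_event	died in	preceding
life_event	passed away	preceding
life_event	was married	preceding
life_event	was admitted	preceding
life_event	was diagnosed	preceding
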