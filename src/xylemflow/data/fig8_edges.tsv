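# Ohm's-law analogue of a heterogeneously connected five-vessel xylem network.
# Five vessels of two lumen elements each (normalized resistance 0.25 per
# element) span a unit pressure difference between the upstream node U (P=1)
# and the downstream node D (P=0); end/side-wall resistors have resistance 1.
# Wiring reconstructed from the published element flows and observed:
# theoretical conductance ratios of the three panel variants, which determine
# it up to a top/bottom mirror.  Columns: kind, vessel, element, node_a,
# node_b, resistance.
kind	vessel	element	node_a	node_b	resistance
lumen	top_left	upstream	U	TLm	0.25
lumen	top_left	downstream	TLm	TL1	0.25
lumen	bottom_left	upstream	U	BLm	0.25
lumen	bottom_left	downstream	BLm	BL1	0.25
lumen	central	upstream	C0	Cm	0.25
lumen	central	downstream	Cm	C1	0.25
lumen	top_right	upstream	TR0	TRm	0.25
lumen	top_right	downstream	TRm	D	0.25
lumen	bottom_right	upstream	BR0	BRm	0.25
lumen	bottom_right	downstream	BRm	D	0.25
wall	-	-	TL1	C0	1.0
wall	-	-	BLm	C0	1.0
wall	-	-	TL1	TR0	1.0
wall	-	-	TLm	BR0	1.0
wall	-	-	TLm	BLm	1.0
wall	-	-	C1	BRm	1.0
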