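strain	lactose	xylitol	melibiose	gluconate	ribose	D-fructose	arbutine	L-arabitol	L-arabinose	glucose	glycerol	mannose	galactose	inositol	erythritol	adonitol	esculine	D-arabinose	D-xylose	L-xylose	beta-methylxyloside	L-sorbose	sorbitol	rhamnose	dulcitol	mannitol	alpha-methyl	D-mannoside	alpha-methyl-D-glucoside	N-acetylglucosamine	amygdaline	saliciline	cellobiose	maltose	sucrose	trehalose	inuline	melezitose	D-raffinose	starch	glycogen	D-turanose	beta-gentibiose	D-tagatose	D-fucose	L-fucose	D-arabitol	2-cetogluconate	5-cetogluconate	D-lyxose
CIRM-BIA9	1	0	0	0.75	0.75	1	0	0.5	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA118	1	0	0	0	0.75	0.75	0	0	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA119	1	0	0	0.75	0	1	0.75	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA121	0	0	0	0.75	0.25	1	0	0.75	0.5	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA122	1	0	0	0	1	0.5	0	0.25	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA123	1	0	0	0.75	0.5	0.75	1	0	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA125	1	0	0	0	0.25	0	0.75	0	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA127	0	0	0	0.5	0.5	0.75	0	0.5	0.5	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA129	1	0	0	0.75	0	1	0.75	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA134	1	0	0	0.75	0	0.75	0	0.75	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA135	1	0	0	0.75	0	0.75	0.75	0	0.25	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA138	1	1	0	0.75	0	0.75	0	0	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA139	1	0	0	0.5	0	0.75	0	0.5	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA456	1	0	0	0.75	0	0.75	0	0	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA508	1	0	0	0	0.75	0.75	0	0	0	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA512	1	0	0	0.5	0.75	0.75	0	0.75	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA513	1	1	1	0.5	0	1	0	0.5	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA514	0	0	0	0.5	0	0	0	0.75	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA516	1	0	0	0.75	0.75	0.75	0	0.75	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA527	0	0	0	0.75	0	0	0	0	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CIRM-BIA1025	1	0	0	0.75	0.25	0.75	1	0	0.75	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
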