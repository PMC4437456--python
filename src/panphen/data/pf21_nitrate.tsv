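strain	nitrate
CIRM-BIA9	0
CIRM-BIA118	0
CIRM-BIA119	1
CIRM-BIA121	1
CIRM-BIA122	1
CIRM-BIA123	0
CIRM-BIA125	0
CIRM-BIA127	1
CIRM-BIA129	0
CIRM-BIA134	0
CIRM-BIA135	0
CIRM-BIA138	1
CIRM-BIA139	1
CIRM-BIA456	0
CIRM-BIA508	0
CIRM-BIA512	0
CIRM-BIA513	0
CIRM-BIA514	1
CIRM-BIA516	1
CIRM-BIA527	1
CIRM-BIA1025	0
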