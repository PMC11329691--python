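# Placeholder reference-connection set: 34 directed pairs over the 18-nucleus
# core panel, drawn from the classical lemniscal / paralemniscal / descending
# motor literature. Users calibrating against their own curated list should
# replace this file.
source	target
PSV	VPM
PSV	PO
PSV	SC
SPVi	PO
SPVi	VII
SPVi	VPM
SPVc	VPM
SPVc	VII
SPVc	PO
SPVo	VPM
VPM	bfd
VPM	RT
PO	bfd
PO	MOp
PO	RT
bfd	VPM
bfd	PO
bfd	MOp
bfd	SC
bfd	ZI
bfd	SPVi
MOp	bfd
MOp	SC
MOp	PO
MOp	VPM
MOp	ZI
MOp	VII
SC	VII
SC	ZI
SC	PPN
RT	VPM
RT	PO
ZI	PO
ZI	VPM
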