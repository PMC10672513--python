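# Fixture corpus of shorthand lipid species names.
# Covers all 15 classes, both separators, parenthesised and bare dialects,
# chain-specified and sum-composition (unresolved) species, odd-carbon and
# very short chains.
DG(16:0_18:1)
DG(14:0/18:2)
DG 16:1_18:3
TG(16:0_16:0_16:0)
TG(16:0_18:1_18:2)
TG(10:2/16:1/24:2)
TG 15:0_17:0_18:1
CL(16:1_18:1_18:2_18:3)
CL(18:2/18:2/18:2/18:2)
PC(16:0_18:2)
PC(18:1/18:1)
PC 16:0_16:0
PE(16:0_22:6)
PE(18:0_20:4)
PG(10:2_24:2)
PG(18:1_18:2)
PI(16:0_18:2)
PS(18:0_18:1)
LPC(16:0)
LPC 18:1
LPC(17:1)
DGe(22:3e)
DGe(16:0e_18:1)
TGe(32:1e)
TGe(34:2e)
TGe(20:0e_16:1_18:1)
PCe(20:0e_14:1)
PEe(36:0e)
PEe(12:0e_22:6)
PEe(16:0e/20:4)
PEp(12:0p_24:2)
PEp(18:0p_18:1)
PEp 10:0p_24:0
PSe(38:5e)
PSe(18:0e_20:4)
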