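"""Grantham (1974) physicochemical distance between amino acids.

Used as the default deleteriousness score for missense changes; the scale
runs from 5 (Leu/Ile, most conservative) to 215 (Cys/Trp, most radical).
"""

from __future__ import annotations

_PAIRS = """
SR110 SL145 SP74 ST58 SA99 SV124 SG56 SI142 SF155 SY144 SC112 SH89 SQ68 SN46 SK121 SD65 SE80 SM135 SW177
RL102 RP103 RT71 RA112 RV96 RG125 RI97 RF97 RY77 RC180 RH29 RQ43 RN86 RK26 RD96 RE54 RM91 RW101
LP98 LT92 LA96 LV32 LG138 LI5 LF22 LY36 LC198 LH99 LQ113 LN153 LK107 LD172 LE138 LM15 LW61
PT38 PA27 PV68 PG42 PI95 PF114 PY110 PC169 PH77 PQ76 PN91 PK103 PD108 PE93 PM87 PW147
TA58 TV69 TG59 TI89 TF103 TY92 TC149 TH47 TQ42 TN65 TK78 TD85 TE65 TM81 TW128
AV64 AG60 AI94 AF113 AY112 AC195 AH86 AQ91 AN111 AK106 AD126 AE107 AM84 AW148
VG109 VI29 VF50 VY55 VC192 VH84 VQ96 VN133 VK97 VD152 VE121 VM21 VW88
GI135 GF153 GY147 GC159 GH98 GQ87 GN80 GK127 GD94 GE98 GM127 GW184
IF21 IY33 IC198 IH94 IQ109 IN149 IK102 ID168 IE134 IM10 IW61
FY22 FC205 FH100 FQ116 FN158 FK102 FD177 FE140 FM28 FW40
YC194 YH83 YQ99 YN143 YK85 YD160 YE122 YM36 YW37
CH174 CQ154 CN139 CK202 CD154 CE170 CM196 CW215
HQ24 HN68 HK32 HD81 HE40 HM87 HW115
QN46 QK53 QD61 QE29 QM101 QW130
NK94 ND23 NE42 NM142 NW174
KD101 KE56 KM95 KW110
DE45 DM160 DW181
EM83 EW152
MW67
"""

GRANTHAM: dict[tuple[str, str], int] = {}
for token in _PAIRS.split():
    a, b, d = token[0], token[1], int(token[2:])
    GRANTHAM[(a, b)] = d
    GRANTHAM[(b, a)] = d
for aa in "ARNDCQEGHILKMFPSTWYV":
    GRANTHAM[(aa, aa)] = 0

MAX_GRANTHAM = 215


def grantham_distance(ref_aa: str, alt_aa: str) -> int:
    """Distance between two amino acids (one-letter codes)."""
    try:
        return GRANTHAM[(ref_aa, alt_aa)]
    except KeyError:
        raise KeyError(f"no Grantham distance for {ref_aa!r}->{alt_aa!r}")
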