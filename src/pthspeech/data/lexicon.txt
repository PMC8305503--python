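# ARPAbet pronunciations (CMU-style, with stress digits) covering the five
# fixed sentence-reading prompts. Vowel nuclei are the phones that carry a
# stress digit.
A  AH0
AFTERNOON  AE2 F T ER0 N UW1 N
AN  AE1 N
BE  B IY1
BECAUSE  B IH0 K AH1 Z
BEST  B EH1 S T
CENTER  S EH1 N T ER0
CHAIN  CH EY1 N
CHAIRMAN  CH EH1 R M AH0 N
COFFEE  K AA1 F IY0
COMMITTEE  K AH0 M IH1 T IY0
DECIDED  D IH0 S AY1 D IH0 D
DEPARTMENT  D IH0 P AA1 R T M AH0 N T
DONATED  D OW1 N EY2 T IH0 D
DONUTS  D OW1 N AH2 T S
DOWN  D AW1 N
FAMOUS  F EY1 M AH0 S
GARDEN  G AA1 R D AH0 N
IN  IH0 N
MAKE  M EY1 K
MANAGEMENT  M AE1 N AH0 JH M AH0 N T
MEETING  M IY1 T IH0 NG
MET  M EH1 T
MONEY  M AH1 N IY0
MORE  M AO1 R
MUCH  M AH1 CH
MUST  M AH1 S T
OF  AH1 V
OPEN  OW1 P AH0 N
OVER  OW1 V ER0
PAVE  P EY1 V
POOR  P UW1 R
SERVE  S ER1 V
SHOP  SH AA1 P
SHOPPING  SH AA1 P IH0 NG
SHUT  SH AH1 T
STANDARDS  S T AE1 N D ER0 D Z
SUCCEED  S AH0 K S IY1 D
SUPERMARKET  S UW1 P ER0 M AA2 R K AH0 T
THE  DH AH0
THEY  DH EY1
THIS  DH IH1 S
TO  T UW1
TOWN  T AW1 N
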