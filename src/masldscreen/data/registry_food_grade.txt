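# Local stand-in for GRAS / Novel-Food membership checks (synthetic list, editable).
# One entry per line: 14-character InChIKey connectivity block, optional name after whitespace.
TZBJGXHYKVUXJN  genistein
REFJWTPEDVJJIY  quercetin
IKGXIBQEEMLURG  rutin
IQPNAANSBPBGFQ  luteolin
IKMDFBPHZNJCSN  myricetin
IKIIZLYTISPENI  baicalin
GZSOSUNBTXMUFQ  diosmin
IYRMWMYZSQPJKC  kaempferol
FTVWIRXFELQLPI  naringenin
PFTAWBLQPZVEMU  epicatechin
QUQPHWDTPGMPEX  hesperidin
KZNIFHPLKGYRTM  apigenin
LUKBXSAWLPMMSZ  resveratrol
VFLDPWHFBUODDF  curcumin
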