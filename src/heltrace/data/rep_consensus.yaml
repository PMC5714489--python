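# Default Rep catalytic-core consensus: three motifs in N- to C-terminal order.
# Pattern alphabet: uppercase letter = exact residue; h = hydrophobic class;
# s = small class; x = any residue.  Edit freely; heltrace treats this file as
# configuration, not code.
class_sets:
  h: "AVLIMFWYC"
  s: "AGSTCNDP"
motifs:
  - "WhxshExxhQ"
  - "HxHhxxhsDh"
  - "YxxKYhsxKh"
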