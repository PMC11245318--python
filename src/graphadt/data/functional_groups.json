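{
  "nitro": "[NX3](~[OX1])~[OX1]",
  "ester": "[CX3](=O)[OX2][#6]",
  "ether": "[OD2]([#6])[#6]",
  "tertiary_amine": "[NX3;H0]([#6])([#6])[#6]",
  "chlorobenzene": "Cl[c]",
  "trichloromethyl": "C(Cl)(Cl)Cl",
  "phenol": "[OX2H][c]",
  "cyano": "[CX2]#[NX1]",
  "phosphoryl": "[PX4]=O",
  "halogenated_hydrocarbon": "[#6][F,Cl,Br,I]"
}
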