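{
  "version": "table-ref16-default",
  "locus_order": [
    "XmnI_Ggamma",
    "HindIII_Ggamma",
    "HindIII_Agamma",
    "HincII_psibeta3",
    "HinfI_beta5"
  ],
  "classical": {
    "Benin": "----+",
    "Bantu/CAR": "-+---",
    "Senegal": "++-++",
    "Cameroon": "-++-+",
    "Arab-Indian": "++--+"
  },
  "atypical": {
    "atypical I": "---++",
    "atypical II": "+---+",
    "atypical III": "-+-+-",
    "atypical IV": "+++-+",
    "atypical V": "--+--"
  }
}
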