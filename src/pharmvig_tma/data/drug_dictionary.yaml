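# Study drug dictionary: generic name -> class, plus brand/synonym rows.
# Classes: VEGFi = ligand (VEGF) inhibitors, VEGFRi = receptor tyrosine-kinase
# or receptor-targeting inhibitors.
generics:
  bevacizumab: VEGFi
  ranibizumab: VEGFi
  brolucizumab: VEGFi
  aflibercept: VEGFi
  conbercept: VEGFi
  pegaptanib: VEGFi
  ramucirumab: VEGFRi
  nintedanib: VEGFRi
  apatinib: VEGFRi
  axitinib: VEGFRi
  sunitinib: VEGFRi
  sorafenib: VEGFRi
  regorafenib: VEGFRi
  vandetanib: VEGFRi
  cabozantinib: VEGFRi
  pazopanib: VEGFRi
  lenvatinib: VEGFRi
  anlotinib: VEGFRi
  fruquintinib: VEGFRi
  tivozanib: VEGFRi
  cediranib: VEGFRi
  brivanib: VEGFRi
synonyms:
  avastin: bevacizumab
  mvasi: bevacizumab
  zirabev: bevacizumab
  lucentis: ranibizumab
  beovu: brolucizumab
  eylea: aflibercept
  zaltrap: aflibercept
  ziv-aflibercept: aflibercept
  lumitin: conbercept
  macugen: pegaptanib
  cyramza: ramucirumab
  ofev: nintedanib
  vargatef: nintedanib
  rivoceranib: apatinib
  inlyta: axitinib
  sutent: sunitinib
  nexavar: sorafenib
  stivarga: regorafenib
  caprelsa: vandetanib
  cabometyx: cabozantinib
  cometriq: cabozantinib
  votrient: pazopanib
  lenvima: lenvatinib
  elunate: fruquintinib
  fotivda: tivozanib
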