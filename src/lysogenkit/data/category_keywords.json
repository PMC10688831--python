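[
  ["transposase", ["transposase", "insertion element", "transposon", "is element"]],
  ["lysogeny", ["integrase", "recombinase", "excisionase", "antirepressor", "repressor", "immunity", "cro", "lysogen"]],
  ["methyltransferase", ["methyltransferase", "methylase", "mtase"]],
  ["endonuclease", ["endonuclease", "homing", "nicking", "restriction enzyme"]],
  ["packaging", ["terminase", "packaging"]],
  ["head", ["portal", "capsid", "prohead", "head", "scaffold", "maturation protease", "encapsidation", "connector"]],
  ["tail", ["tape measure", "tail", "baseplate", "sheath", "distal tail"]],
  ["fiber", ["fiber", "fibre", "receptor", "spike", "host specificity", "host recognition", "antireceptor"]],
  ["lysis", ["holin", "lysin", "amidase", "lysozyme", "muramidase", "glucosaminidase", "spanin", "lysis", "peptidoglycan hydrolase"]],
  ["replication", ["replication", "replisome", "helicase", "primase", "polymerase", "single-strand", "single strand", "ssb", "topoisomerase", "recombination protein", "dna-binding", "dna binding"]],
  ["trna", ["tmrna", "transfer-messenger", "trna", "transfer rna"]],
  ["hypothetical", ["hypothetical", "uncharacterized", "uncharacterised", "duf", "unknown function"]]
]
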