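{
  "ide-cel": ["IDECABTAGENE VICLEUCEL", "ABECMA", "BB2121", "BB-2121", "IDE-CEL"],
  "cilta-cel": ["CILTACABTAGENE AUTOLEUCEL", "CARVYKTI", "JNJ-68284528", "CILTA-CEL"],
  "teclistamab": ["TECLISTAMAB", "TECLISTAMAB-CQYV", "TECVAYLI", "JNJ-64007957"]
}
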