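{
  "aliases": {
    "KNTC2": "NDC80",
    "CDCA1": "NUF2",
    "ORC6L": "ORC6"
  }
}
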