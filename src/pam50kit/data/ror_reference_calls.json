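{
  "description": "Published risk-of-recurrence scores and printed risk groups for seven triple-negative breast tumors assayed on both a digital multiplexed platform and RNA-Seq; the pairs whose subtype calls differed between platforms. Used as a worked example to check the default risk-group cutoffs and the risk-group discordance tally (one sample, HLPR-002, changes ROR group between platforms).",
  "samples": [
    {"sample_id": "HCSC-0027", "platform": "nanostring", "ror_s": 51.10, "ror_s_group": "med",  "ror_ps": 43.42,  "ror_ps_group": "med"},
    {"sample_id": "HLPR-002",  "platform": "nanostring", "ror_s": 43.57, "ror_s_group": "med",  "ror_ps": 23.44,  "ror_ps_group": "med"},
    {"sample_id": "HUGM-0022", "platform": "nanostring", "ror_s": 51.60, "ror_s_group": "med",  "ror_ps": 42.28,  "ror_ps_group": "med"},
    {"sample_id": "HUGM-0029", "platform": "nanostring", "ror_s": 73.51, "ror_s_group": "high", "ror_ps": 68.98,  "ror_ps_group": "high"},
    {"sample_id": "HUGM-0047", "platform": "nanostring", "ror_s": 81.24, "ror_s_group": "high", "ror_ps": 72.48,  "ror_ps_group": "high"},
    {"sample_id": "INEN-0017", "platform": "nanostring", "ror_s": 66.66, "ror_s_group": "high", "ror_ps": 55.051, "ror_ps_group": "high"},
    {"sample_id": "INEN-0021", "platform": "nanostring", "ror_s": 72.50, "ror_s_group": "high", "ror_ps": 65.40,  "ror_ps_group": "high"},
    {"sample_id": "HCSC-0027", "platform": "rnaseq",     "ror_s": 35.25, "ror_s_group": "med",  "ror_ps": 33.04,  "ror_ps_group": "med"},
    {"sample_id": "HLPR-002",  "platform": "rnaseq",     "ror_s": 16.87, "ror_s_group": "low",  "ror_ps": 10.68,  "ror_ps_group": "low"},
    {"sample_id": "HUGM-0022", "platform": "rnaseq",     "ror_s": 40.68, "ror_s_group": "med",  "ror_ps": 32.44,  "ror_ps_group": "med"},
    {"sample_id": "HUGM-0029", "platform": "rnaseq",     "ror_s": 75.02, "ror_s_group": "high", "ror_ps": 69.59,  "ror_ps_group": "high"},
    {"sample_id": "HUGM-0047", "platform": "rnaseq",     "ror_s": 73.73, "ror_s_group": "high", "ror_ps": 69.58,  "ror_ps_group": "high"},
    {"sample_id": "INEN-0017", "platform": "rnaseq",     "ror_s": 62.68, "ror_s_group": "high", "ror_ps": 52.98,  "ror_ps_group": "high"},
    {"sample_id": "INEN-0021", "platform": "rnaseq",     "ror_s": 66.98, "ror_s_group": "high", "ror_ps": 64.52,  "ror_ps_group": "high"}
  ]
}
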