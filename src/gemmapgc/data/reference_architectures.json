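{
 "version": 1,
 "comment": "Block-level PGC layouts. gemma-template is the Gemmatimonadetes-type architecture; the proteobacterial variants are synthetic stand-ins encoding plausible per-class permutations, not transcriptions of any deposited genome.",
 "architectures": {
  "gemma-template": [
   [
    "aerR",
    "-"
   ],
   [
    "ppsR",
    "-"
   ],
   [
    "bchP2G",
    "+"
   ],
   [
    "bchFNBHLM",
    "+"
   ],
   [
    "acsF",
    "+"
   ],
   [
    "lhaA-puhABC",
    "+"
   ],
   [
    "puhE",
    "+"
   ],
   [
    "pufBALMC",
    "+"
   ],
   [
    "bchO",
    "+"
   ],
   [
    "crtF-bchCXYZ",
    "-"
   ],
   [
    "bchID",
    "-"
   ]
  ],
  "proteo-alpha-1-synthetic": [
   [
    "crtF-bchCXYZ",
    "-"
   ],
   [
    "bchO",
    "-"
   ],
   [
    "ppsR",
    "+"
   ],
   [
    "bchFNBHLM",
    "+"
   ],
   [
    "lhaA-puhABC",
    "+"
   ],
   [
    "acsF",
    "+"
   ],
   [
    "puhE",
    "+"
   ],
   [
    "bchID",
    "+"
   ],
   [
    "bchP2G",
    "+"
   ],
   [
    "pufBALMC",
    "-"
   ],
   [
    "aerR",
    "+"
   ]
  ],
  "proteo-alpha-2-synthetic": [
   [
    "ppsR",
    "-"
   ],
   [
    "aerR",
    "-"
   ],
   [
    "bchP2G",
    "-"
   ],
   [
    "bchFNBHLM",
    "+"
   ],
   [
    "lhaA-puhABC",
    "+"
   ],
   [
    "puhE",
    "+"
   ],
   [
    "pufBALMC",
    "+"
   ],
   [
    "bchO",
    "+"
   ],
   [
    "crtF-bchCXYZ",
    "+"
   ],
   [
    "bchID",
    "+"
   ],
   [
    "acsF",
    "+"
   ]
  ],
  "proteo-beta-synthetic": [
   [
    "bchID",
    "+"
   ],
   [
    "bchP2G",
    "+"
   ],
   [
    "bchFNBHLM",
    "+"
   ],
   [
    "acsF",
    "+"
   ],
   [
    "lhaA-puhABC",
    "+"
   ],
   [
    "puhE",
    "+"
   ],
   [
    "pufBALMC",
    "+"
   ],
   [
    "crtF-bchCXYZ",
    "+"
   ],
   [
    "bchO",
    "+"
   ],
   [
    "aerR",
    "-"
   ],
   [
    "ppsR",
    "-"
   ]
  ],
  "proteo-gamma-synthetic": [
   [
    "pufBALMC",
    "-"
   ],
   [
    "lhaA-puhABC",
    "-"
   ],
   [
    "puhE",
    "-"
   ],
   [
    "acsF",
    "-"
   ],
   [
    "bchFNBHLM",
    "-"
   ],
   [
    "bchP2G",
    "-"
   ],
   [
    "bchID",
    "+"
   ],
   [
    "crtF-bchCXYZ",
    "+"
   ],
   [
    "bchO",
    "+"
   ],
   [
    "ppsR",
    "+"
   ],
   [
    "aerR",
    "+"
   ]
  ]
 }
}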