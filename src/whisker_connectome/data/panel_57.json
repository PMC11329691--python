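{
  "core18": [
    "bfd", "MOp", "SI", "VII", "SC", "RT", "ZI", "VPM", "PO",
    "PSV", "SPVi", "SPVc", "SPVo", "VTA", "LC", "DR", "TM", "PPN"
  ],
  "extended57": [
    "bfd", "MOp", "SI", "VII", "SC", "RT", "ZI", "VPM", "PO",
    "PSV", "SPVi", "SPVc", "SPVo", "VTA", "LC", "DR", "TM", "PPN",
    "MOs", "CLA", "SSp-m", "SSs", "ACAd",
    "VAL", "VM", "PF", "CL", "MD", "LP",
    "PAG", "RN", "MRN", "APN", "SNr", "SNc",
    "GRN", "IRN", "PARN", "NTS", "IO",
    "PB", "PRN", "PG", "SOC", "TRN",
    "CP", "ACB",
    "FN", "IP", "DN",
    "CEA", "LA", "BLA",
    "LHA", "STN",
    "GP", "BST"
  ],
  "neuromodulatory": ["VTA", "LC", "DR", "TM", "PPN", "SI"],
  "groups": {
    "bfd": "cortex",
    "MOp": "cortex",
    "SI": "pallidum",
    "VII": "medulla",
    "SC": "midbrain",
    "RT": "thalamus",
    "ZI": "hypothalamus",
    "VPM": "thalamus",
    "PO": "thalamus",
    "PSV": "hindbrain",
    "SPVi": "medulla",
    "SPVc": "medulla",
    "SPVo": "medulla",
    "VTA": "midbrain",
    "LC": "hindbrain",
    "DR": "midbrain",
    "TM": "hypothalamus",
    "PPN": "midbrain",
    "MOs": "cortex",
    "CLA": "cortex",
    "SSp-m": "cortex",
    "SSs": "cortex",
    "ACAd": "cortex",
    "VAL": "thalamus",
    "VM": "thalamus",
    "PF": "thalamus",
    "CL": "thalamus",
    "MD": "thalamus",
    "LP": "thalamus",
    "PAG": "midbrain",
    "RN": "midbrain",
    "MRN": "midbrain",
    "APN": "midbrain",
    "SNr": "midbrain",
    "SNc": "midbrain",
    "GRN": "medulla",
    "IRN": "medulla",
    "PARN": "medulla",
    "NTS": "medulla",
    "IO": "medulla",
    "PB": "hindbrain",
    "PRN": "hindbrain",
    "PG": "hindbrain",
    "SOC": "hindbrain",
    "TRN": "hindbrain",
    "CP": "striatum",
    "ACB": "striatum",
    "FN": "cerebellum",
    "IP": "cerebellum",
    "DN": "cerebellum",
    "CEA": "amygdala",
    "LA": "amygdala",
    "BLA": "amygdala",
    "LHA": "hypothalamus",
    "STN": "hypothalamus",
    "GP": "pallidum",
    "BST": "pallidum"
  }
}
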