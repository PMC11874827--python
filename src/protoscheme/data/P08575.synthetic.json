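{
  "comment": "synthetic stand-in record: true length and representative features of human CD45; sequence-free",
  "features": [
    {
      "description": "",
      "location": {
        "end": {
          "value": 23
        },
        "start": {
          "value": 1
        }
      },
      "type": "Signal"
    },
    {
      "description": "Receptor-type tyrosine-protein phosphatase C",
      "location": {
        "end": {
          "value": 1306
        },
        "start": {
          "value": 24
        }
      },
      "type": "Chain"
    },
    {
      "description": "Extracellular",
      "location": {
        "end": {
          "value": 577
        },
        "start": {
          "value": 24
        }
      },
      "type": "Topological domain"
    },
    {
      "description": "Helical",
      "location": {
        "end": {
          "value": 601
        },
        "start": {
          "value": 578
        }
      },
      "type": "Transmembrane"
    },
    {
      "description": "Cytoplasmic",
      "location": {
        "end": {
          "value": 1306
        },
        "start": {
          "value": 602
        }
      },
      "type": "Topological domain"
    },
    {
      "description": "Fibronectin type-III 1",
      "location": {
        "end": {
          "value": 486
        },
        "start": {
          "value": 391
        }
      },
      "type": "Domain"
    },
    {
      "description": "Fibronectin type-III 2",
      "location": {
        "end": {
          "value": 575
        },
        "start": {
          "value": 491
        }
      },
      "type": "Domain"
    },
    {
      "description": "Tyrosine-protein phosphatase 1",
      "location": {
        "end": {
          "value": 912
        },
        "start": {
          "value": 653
        }
      },
      "type": "Domain"
    },
    {
      "description": "Tyrosine-protein phosphatase 2",
      "location": {
        "end": {
          "value": 1236
        },
        "start": {
          "value": 944
        }
      },
      "type": "Domain"
    },
    {
      "description": "Phosphocysteine intermediate",
      "location": {
        "end": {
          "value": 828
        },
        "start": {
          "value": 828
        }
      },
      "type": "Active site"
    },
    {
      "description": "Phosphoserine",
      "location": {
        "end": {
          "value": 965
        },
        "start": {
          "value": 965
        }
      },
      "type": "Modified residue"
    },
    {
      "description": "Phosphotyrosine",
      "location": {
        "end": {
          "value": 1216
        },
        "start": {
          "value": 1216
        }
      },
      "type": "Modified residue"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 59
        },
        "start": {
          "value": 59
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 111
        },
        "start": {
          "value": 111
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 161
        },
        "start": {
          "value": 161
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 193
        },
        "start": {
          "value": 193
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 223
        },
        "start": {
          "value": 223
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 246
        },
        "start": {
          "value": 246
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 281
        },
        "start": {
          "value": 281
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 302
        },
        "start": {
          "value": 302
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 334
        },
        "start": {
          "value": 334
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 373
        },
        "start": {
          "value": 373
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 416
        },
        "start": {
          "value": 416
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 467
        },
        "start": {
          "value": 467
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "N-linked (GlcNAc...) asparagine",
      "location": {
        "end": {
          "value": 488
        },
        "start": {
          "value": 488
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "O-linked (GalNAc...) threonine",
      "location": {
        "end": {
          "value": 47
        },
        "start": {
          "value": 47
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "O-linked (GalNAc...) threonine",
      "location": {
        "end": {
          "value": 92
        },
        "start": {
          "value": 92
        }
      },
      "type": "Glycosylation"
    },
    {
      "description": "O-linked (GalNAc...) threonine",
      "location": {
        "end": {
          "value": 135
        },
        "start": {
          "value": 135
        }
      },
      "type": "Glycosylation"
    }
  ],
  "primaryAccession": "P08575",
  "proteinDescription": {
    "recommendedName": {
      "fullName": {
        "value": "Receptor-type tyrosine-protein phosphatase C"
      }
    }
  },
  "sequence": {
    "length": 1306
  }
}
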