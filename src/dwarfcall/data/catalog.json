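{
  "loci": [
    {
      "name": "Dw1",
      "gene_id": "Sobic.009G229800",
      "primer_pair": {
        "forward": "TGGCGGTCCAACGTCTAAT",
        "reverse": "CCTGAAGTATGGCGTGTCG"
      },
      "wild_type_amplicon_length": 427
    },
    {
      "name": "Dw2",
      "gene_id": "Sobic.006G067700",
      "primer_pair": {
        "forward": "CAGTTCAAATCAACGAGGAG",
        "reverse": "TCCGTCGTGAAATGAGAATA"
      },
      "wild_type_amplicon_length": 997
    },
    {
      "name": "Dw3",
      "gene_id": "Sobic.007G163800",
      "primer_pair": {
        "forward": "CCGTCATCGTCCAGAACTCG",
        "reverse": "CTTGAGCAGGTGCGAGTGCGA"
      },
      "wild_type_amplicon_length": 1280
    }
  ],
  "alleles": [
    {
      "allele_name": "dw1",
      "locus_name": "Dw1",
      "signature": {"kind": "substitution", "start": 1350, "end": 1350, "length": 1, "alt": "T"},
      "expected_amplicon_length": 427
    },
    {
      "allele_name": "dw2",
      "locus_name": "Dw2",
      "signature": {"kind": "deletion", "start": 549, "end": 550, "length": 2, "alt": ""},
      "expected_amplicon_length": 995
    },
    {
      "allele_name": "dw3-ref",
      "locus_name": "Dw3",
      "signature": {"kind": "insertion", "start": 6204, "end": 7085, "length": 882, "alt": ""},
      "expected_amplicon_length": 2162
    },
    {
      "allele_name": "dw3-a",
      "locus_name": "Dw3",
      "signature": {"kind": "substitution", "start": 5406, "end": 5406, "length": 1, "alt": "C"},
      "expected_amplicon_length": 1280
    },
    {
      "allele_name": "dw3-b",
      "locus_name": "Dw3",
      "signature": {"kind": "substitution", "start": 5668, "end": 5668, "length": 1, "alt": "G"},
      "expected_amplicon_length": 1280
    },
    {
      "allele_name": "dw3-c",
      "locus_name": "Dw3",
      "signature": {"kind": "deletion", "start": 5967, "end": 5968, "length": 2, "alt": ""},
      "expected_amplicon_length": 1278
    },
    {
      "allele_name": "dw3-sd3",
      "locus_name": "Dw3",
      "signature": {"kind": "deletion", "start": 5485, "end": 5566, "length": 82, "alt": ""},
      "expected_amplicon_length": 1198
    },
    {
      "allele_name": "dw3-sd4",
      "locus_name": "Dw3",
      "signature": {"kind": "duplication", "start": 5820, "end": 5825, "length": 6, "alt": ""},
      "expected_amplicon_length": 1286
    },
    {
      "allele_name": "dw3-sd5",
      "locus_name": "Dw3",
      "signature": {"kind": "deletion", "start": 5997, "end": 6011, "length": 15, "alt": ""},
      "expected_amplicon_length": 1265
    }
  ]
}
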