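{
  "note": "Published splice-site windows of the Agdsx gene (2R, reverse strand). Sequences are 5'->3' on the reverse strand, exon/intron boundary marked '/'; coding bases uppercase. site_pos is [5'-most, 3'-most] in transcript order (start > end on the reverse strand). Used to embed the real site sequences into the synthetic reference contig.",
  "donors": [
    {"exon": 1, "gender": "Male/Female", "boundary": 48787046, "site_pos": [48787051, 48787030], "sequence": "tatttg/gtaagtaaatatgcaa"},
    {"exon": 2, "gender": "Male/Female", "boundary": 48784185, "site_pos": [48784190, 48784169], "sequence": "TGGGAG/gtaagtacgatcatgc"},
    {"exon": 3, "gender": "Male/Female", "boundary": 48747693, "site_pos": [48747698, 48747677], "sequence": "TACCTG/gtaagtaaatataatt"},
    {"exon": 4, "gender": "Male/Female", "boundary": 48715161, "site_pos": [48715166, 48715145], "sequence": "ACGAAG/gtaagctggcgatgat"},
    {"exon": 5, "gender": "Female", "boundary": 48712957, "site_pos": [48712962, 48712941], "sequence": "cagaag/gtatggtaagacggcc"},
    {"exon": 6, "gender": "Male/Female", "boundary": 48711528, "site_pos": [48711533, 48711512], "sequence": "aaaaag/gtaagtgtgggtagta"}
  ],
  "acceptors": [
    {"intron": 1, "gender": "Male/Female", "boundary": 48785629, "site_pos": [48785645, 48785624], "sequence": "gtacgtttgattgcag/atctcc"},
    {"intron": 2, "gender": "Male/Female", "boundary": 48747737, "site_pos": [48747753, 48747732], "sequence": "ttgctctccttttcag/CTACTC"},
    {"intron": 3, "gender": "Male/Female", "boundary": 48715295, "site_pos": [48715311, 48715290], "sequence": "ttccgccccgtttcag/ACGACG"},
    {"intron": 4, "gender": "Female", "boundary": 48714648, "site_pos": [48714664, 48714643], "sequence": "tttatgtttaacacag/GTCAAG"},
    {"intron": 4, "gender": "Male", "boundary": 48712794, "site_pos": [48712810, 48712789], "sequence": "tgtaacccccaaaaag/gtaaac"},
    {"intron": 6, "gender": "Male/Female", "boundary": 48706331, "site_pos": [48706347, 48706326], "sequence": "cgcttcctcaaaatag/atcgat"}
  ]
}
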