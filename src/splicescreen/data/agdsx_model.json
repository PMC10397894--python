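{
  "gene_id": "AGAP004050",
  "gene_name": "Agdsx",
  "chrom": "2R",
  "strand": "-",
  "span": [48703664, 48788460],
  "transcripts": [
    {
      "id": "AgdsxF",
      "sex_label": "female",
      "exons": [
        [48787046, 48788460],
        [48784185, 48785629],
        [48747693, 48747737],
        [48715161, 48715295],
        [48712957, 48714648],
        [48711528, 48712794],
        [48703664, 48706331]
      ]
    },
    {
      "id": "AgdsxM",
      "sex_label": "male",
      "exons": [
        [48787046, 48788460],
        [48784185, 48785629],
        [48747693, 48747737],
        [48715161, 48715295],
        [48711528, 48712794],
        [48703664, 48706331]
      ]
    }
  ],
  "cds": {
    "AgdsxF": [
      [48784185, 48785483],
      [48747693, 48747737],
      [48715161, 48715295],
      [48713041, 48714648]
    ]
  },
  "cds_note": "Coding span of the female transcript. UTR boundaries at splice windows are annotation-accurate; interior start/stop placement is approximate and only used to render case."
}
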