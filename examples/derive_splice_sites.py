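"""Derive the doublesex splice-site table from the packaged gene model.

Builds the default synthetic reference (the real 22-nt site sequences
embedded at their genomic coordinates, random elsewhere), derives every
donor/acceptor window, and prints the site table. The sequences, window
positions, exon/intron sizes and sharing labels match the published gene
annotation; acceptor rows additionally carry the pyrimidine count of their
12-nt tract (8 for the female-specific intron 4, close to the species
consensus of 8.69 — not a weak acceptor).
"""

import splicescreen as ss

gene = ss.load_packaged_gene()
reference = ss.make_reference(ss.SimulationConfig(seed=1))
cds = ss.load_packaged_cds()

print(f"gene {gene.gene_id} on {gene.chrom} ({gene.strand} strand), "
      f"span {gene.span.low:,}-{gene.span.high:,}")
for t in gene.transcripts:
    print(f"  {t.id}: {t.n_exons} exons, spliced length {ss.transcript_length(t):,} bp")

for c in ss.detect_cassette_exons(gene):
    print(f"cassette exon: {c.exon_transcript} exon {c.exon_ordinal} "
          f"[{c.exon.low:,}-{c.exon.high:,}] skipped inside "
          f"{c.host_transcript} intron {c.host_intron_ordinal}")

df = ss.site_table(gene, reference, cds)
print()
print(df[["kind", "sharing", "site_pos_start", "site_pos_end",
          "sequence", "pyrimidine_count"]].to_string(index=False))
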