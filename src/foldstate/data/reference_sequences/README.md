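# Reference sequences

Place the published reference FASTA files here to enable the
accession-based composition checks:

- `CNAG_03291.fasta` — full-length CnGRASP (Broad Institute accession
  CNAG_03291; 256 residues, theoretical average mass 27,551.7 Da)
- `CAA68468.1.fasta` — Conalbumin (GenBank CAA68468.1)
- `AAB59956.1.fasta` — Ovalbumin (GenBank AAB59956.1)
- `CAA76847.1.fasta` — Bovine Serum Albumin (GenBank CAA76847.1)

They are one-time downloads from the public archives (e.g. NCBI efetch)
and are not bundled with the package.
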