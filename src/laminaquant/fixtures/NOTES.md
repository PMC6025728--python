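# Fixture transcription notes

These TSVs are transcriptions of the published primer/probe table, the
splice-variant prediction/confirmation table and the 28-gene summary table
of the source study, plus a per-age dependency-call matrix encoded from the
per-age significance levels reported in the running text.

Conventions and caveats:

* `table1.tsv` — the published table prints the forward and reverse primer
  columns adjacent; in the text extraction used for transcription the two
  sequences are concatenated without a separator.  Splits were recovered
  where a primer recurs across rows (the shared reverse primers pr.9 =
  `CTGAGATTTCCTCATCGTTCCT` and pr.8 = `CGGGTTAAGGGAAGTCAAATTC` pin down all
  Clcc1 rows, and pr.5 pins down the Pnkd rows); the remaining 3'-UTR rows
  assume a ~20 nt forward primer and the split point there is a best-effort
  guess.  Product sizes, T3 extension and incubation times are unambiguous.
  `usage`: `rtpcr_only` rows are marked `^` in the original, `ish_only`
  rows `^^`; `rtpcr_negative=yes` corresponds to `*`.
* `table2.tsv` — multi-band reactions list comma-separated sizes.
  `detected_transcripts` carries the `^` detection marks; `all` means every
  annotated isoform.  Three Clcc1 pairs (pr.3+pr.8, pr.4+pr.8, pr.6+pr.8)
  appear only in the original table's legend, not in the primer table.
* `table3.tsv` — flags are `yes`/`no` (`na` where the original prints no
  call); `onset`/`peak`/`offset` are ages, `none`, or a plateau range such
  as `P7-P14`.  Exactly 28 gene rows.
* `dependency_matrix.tsv` — per-age Brn3a-dependency calls encoded from the
  per-age p-values the running text reports for each gene; ages without a
  reported significant differential are `no`.  The Tusc5 row is encoded as
  significant at all five ages, per the reported near-complete knockout
  loss and the summary-table flags.

`checksums.json` holds SHA-256 digests of the fixture TSVs; the loader
verifies them.
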