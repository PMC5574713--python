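# Published indel catalogs (not bundled)

Two acceptance tests (`test_published_catalog_totals`,
`test_published_catalog_context_statistics`) verify context statistics
recomputed from the published *E. coli* / *Buchnera* transcription-indel
catalogs. Those catalogs are journal supplementary material and are not
redistributed here; to run the checks, download Data Sets S1–S4 from the
article's supplementary material (doi:10.1128/mBio.01230-17), export each
sheet as tab-separated text, and place the files here as:

    data/dataset_s1.tsv   # E. coli deletions      (921 rows)
    data/dataset_s2.tsv   # E. coli insertions     (72 rows)
    data/dataset_s3.tsv   # Buchnera deletions     (70 rows)
    data/dataset_s4.tsv   # Buchnera insertions    (157 rows)

Each file needs the six-column header

    source_id	replicate	location	upstream	event_seq	downstream

followed by one row per event exactly as deposited (SRA accession, biological
replicate, 1-based genomic location, nine upstream bases, the
inserted/deleted sequence, downstream bases). Without these files the two
tests fail with a message pointing here; everything else in the package runs
on generated data.
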