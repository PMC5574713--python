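"""Classify the bundled worked-example insertions by backward slippage.

The fixture holds the 19 transcription insertions found outside
homopolymeric runs in the E. coli transcriptome. An insertion is
slippage-consistent when the inserted bases duplicate the bases transcribed
immediately before it — the signature of the polymerase slipping backward
and retranscribing.
"""

from txslip import classify_insertion, load_table1_fixture

records = load_table1_fixture()
n_yes = 0
for rec in records:
    flag = classify_insertion(rec)
    n_yes += flag
    mark = "slippage" if flag else "other   "
    print(f"{mark}  {rec.upstream:>11s} + [{rec.event_seq}]  {rec.downstream}")

print(f"\n{n_yes} of {len(records)} insertions duplicate their preceding bases")
print("(the longest duplicates the preceding "
      f"{max(len(r.event_seq) for r in records)} nucleotides)")
# The count is the fraction of non-homopolymer insertions explainable by
# backward slippage followed by retranscription of the slipped region.
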