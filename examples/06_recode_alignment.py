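"""Four-state amino-acid recoding.

Deep bacterial phylogenies suffer from compositional heterogeneity:
unrelated lineages with similar amino-acid composition can be drawn
together.  Recoding the 20 amino acids into 4 physicochemical groups
(written as nucleotide symbols) suppresses much of that signal.
"""

from endoclock import Alignment, recode_alignment

aln = Alignment(
    names=["Rickettsia", "Mito_plant", "Mito_jakobid"],
    seqs=["MKTAYIAKQR-QISFVKSHFSRQ",
          "MKSAYLAKQR-EISFIKDHFARQ",
          "MRTAYIGKPR-QLSWVKNHFTXQ"],
)

for scheme in ("dayhoff4", "sr4"):
    out = recode_alignment(aln, scheme)
    print(f"{scheme}:")
    for name, seq in zip(out.names, out.seqs):
        print(f"  {name:14s} {seq}")

print("\nGaps (-) and ambiguities (X) pass through unchanged; under")
print("dayhoff4, cysteine has no group and is masked to X.")
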