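"""Predict translational recoding in an IS-element transposase.

Builds a -1 frameshift element (two overlapping ORFs joined by the
slippery heptamer AAAAAAG with a stimulatory downstream hairpin) and a
stop-codon read-through element (internal UGA-A quartet), then shows what
the recoding caller reports for each.
"""

from iscensus import (FamilySpec, GenomeRecord, call_recoding, find_orfs,
                      find_slippery_sites, fold_hairpin)
from iscensus.synthetic import consensus_with_info

for arch, length in (("overlap_minus1", 914), ("readthrough", 881)):
    spec = FamilySpec("demo", length, orf_architecture=arch,
                      family_class="IS5")
    info = consensus_with_info(spec, seed=7)
    orfs = find_orfs(GenomeRecord("element", info.seq), min_protein_len=80)
    fwd = [o for o in orfs if o.interval.strand == "+"]
    call = call_recoding(info.seq, orfs)

    print(f"== {arch} element, {length} bp, "
          f"{len(fwd)} forward ORFs: {[(o.interval.start, o.interval.end) for o in fwd]}")
    print(f"   call: {call.kind}, merged transframe protein "
          f"{call.merged_protein_len} aa")
    if call.kind == "minus1":
        s = call.site
        print(f"   slippery site {s.heptamer} at {s.position}; "
              f"stimulatory hairpin "
              + (f"dG {call.hairpin.dG} kcal/mol at {call.hairpin.start}"
                 if call.hairpin else "not required for AAAAAAG"))
    if call.kind == "readthrough":
        p = call.site
        print(f"   weak stop {info.seq[p:p+4]} (UGA-A quartet) at {p}; "
              f"translation continues in frame")
    print()

print("A frameshift or read-through fuses the ORFs into one transposase;")
print("the merged protein is what carries the complete catalytic domain.")
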