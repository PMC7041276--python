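"""The bisulfite-aware match rule and seed-and-extend alignment.

A fully converted read (every unmethylated C sequenced as T) still aligns
to its hairpin because read-T over reference-C is an authorized
substitution; the reverse (read-C over reference-T) never is.
"""

from mirbs.bsalign import (
    AlignParams, MatchPolicy, align_read, base_match, build_seed_index,
)
from mirbs.readqc import CollapsedRead
from mirbs.refio import HairpinReference, MatureAnnotation

converted = MatchPolicy(converted_mode=True)
print("base_match(ref=C, read=T, converted) ->", base_match("C", "T", converted))
print("base_match(ref=T, read=C, converted) ->", base_match("T", "C", converted))

hairpin = HairpinReference.from_sequence(
    "hsa-mir-demo",
    "GGAUAG" + "UACGAUUCGCUAAGGCAUGA" + "GGAUAG",   # mature arm at [6, 26)
    [MatureAnnotation("hsa-miR-demo-5p", 6, 26)],
)
print("\nhairpin CpG positions:", hairpin.cpg_positions)
print("non-CpG C positions:  ", hairpin.noncpg_c_positions)

mature_seq = hairpin.sequence[6:26]
fully_converted = mature_seq.replace("C", "T")
read = CollapsedRead("u1_x40", fully_converted, 40)

index = build_seed_index([hairpin], converted, k=12)
(aln,) = align_read(read, index, converted, AlignParams())
print(f"\nread {read.sequence} (40 copies)")
print(f"aligned to {aln.hairpin_id}[{aln.ref_start}:{aln.ref_end}], "
      f"{aln.tc_conversions} T-C conversion calls")
for pos, state in aln.cytosine_calls:
    context = "CpG" if pos in hairpin.cpg_positions else "non-CpG"
    print(f"  ref C at {pos:>3} ({context}): {state}")
# every reference C in the span is classified: converted_T here, because the
# read was generated fully converted (no methylation, perfect chemistry).
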