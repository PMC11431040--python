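"""Build the bundled synthetic mRNA construct and inspect its primer sections.

Each RT primer reads the template interval between its own pairing start and
the previous primer's, so six primers tile a ~2.8 kb mRNA into six ~500-nt
sections; the poly(A) tail downstream of the last primer is never read.
"""
from mprtseq import reference_bundle

bundle = reference_bundle()
construct = bundle.construct

print(f"construct: {construct.name}, {len(construct)} nt")
for label, start, end in construct.elements:
    print(f"  {label:12s} {start:5d}-{end}")

print("\nposition 1986 lies in:", construct.element_at(1986))

print("\nsection map (primer, covered interval):")
for sec in bundle.section_map:
    width = sec.covered_end - sec.covered_start + 1
    print(f"  {sec.primer}: {sec.covered_start:5d}-{sec.covered_end} ({width} nt)")
print(f"unread 3' of position {bundle.section_map.uncovered_start - 1} (poly(A) tail)")
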