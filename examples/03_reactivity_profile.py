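"""From simulated RT-stop peak tables to one assembled reactivity profile.

A chain break at template position p makes the reverse transcriptase stop
there, producing a cDNA of length (pairing_start - p); mapping peak sizes
back and merging the six primer sections gives a per-nucleotide degradation
profile. Subtracting the untreated control removes the full-length
background.
"""
import numpy as np

from mprtseq import (
    CleavageModel,
    StressDose,
    assemble_sections,
    cleavage_propensity,
    mean_reactivity,
    peaks_to_positions,
    reference_bundle,
    simulate_fragments,
    simulate_rt_traces,
    subtract_control,
)

bundle = reference_bundle()
construct = bundle.construct
model = CleavageModel.for_regime("freeze_thaw")
propensity = cleavage_propensity(construct, bundle.structure, model)


def profile_at(cycles, seed):
    pop = simulate_fragments(
        propensity, StressDose("freeze_thaw", cycles), 10_000, seed,
        model.per_event_rate,
    )
    tables = simulate_rt_traces(pop, construct.primers)
    maps = {t.primer: peaks_to_positions(t, p)
            for t, p in zip(tables, construct.primers)}
    return assemble_sections(maps, construct.section_map(), len(construct),
                             primers=construct.primers)


control = profile_at(0, seed=1)
for cycles in [5, 10, 20]:
    prof = subtract_control(profile_at(cycles, seed=1), control)
    top = np.nanargmax(prof.values) + 1
    print(f"{cycles:2d} cycles: mean reactivity {mean_reactivity(prof):.3f} "
          f"(stop counts per read position), strongest site {top} "
          f"({construct.base_at(top)}, {construct.element_at(top)})")
print("\nmean reactivity grows with dose while CE integrity falls — the same "
      "degradation seen at single-nucleotide instead of whole-molecule scale")
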