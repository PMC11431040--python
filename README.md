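# mprtseq

Single-nucleotide mapping of mRNA degradation by multi-primer
reverse-transcription (RT-stop) profiling, with capillary-electrophoresis
(CE) integrity QC and secondary-structure context annotation.

## The problem

mRNA therapeutics degrade in storage mainly by in-line transesterification:
the 2′-OH attacks its own backbone phosphate and the chain breaks. Standard
QC — capillary electrophoresis of the fragment smear — reports *how much*
of the material is still full length, but not *where* the chain breaks,
so it offers no handle for designing more stable sequences.

Primer-extension chemistry closes that gap. A reverse transcriptase
initiated from a labelled primer stops wherever the template is cleaved;
sizing the cDNA pool maps every break to a nucleotide. Because a single RT
read covers only ~300–650 nt, a multi-kilobase mRNA is tiled with several
5′-FAM-labelled primers — here six, each reading the ~500-nt section
between its own pairing site and the previous primer's — and the sections
are assembled into one per-nucleotide *degradation reactivity* profile.

## The method in brief

For a primer pairing at position `s`, a cDNA of length `k` means an RT stop
(= chain break) at template position `s − k`. Per-primer stop intensities
are assembled section-wise into a 1..L profile, optionally box-plot
normalized (mean of the 8% of values below the top 2%), and referenced to
an untreated control by subtraction (negatives clamp to zero).

High-intensity positions are defined against a rescaled average line

&nbsp;&nbsp;&nbsp;&nbsp; *I<sub>A</sub>(N) = A (1 + q)<sup>N</sup>*

where *A* is the regime's total average degradation reactivity, *q* a small
rescale factor and *N* the nucleotide position. Runs of above-line
positions (gap ≤ 3, ≥ 2 members) that occur in **both** stress regimes —
freeze–thaw cycling and 37 °C incubation — become hotspot calls, each
annotated with its fold change over *A*, base composition, and
secondary-structure context (5′ stem strand / apical loop / mid-stem bulge)
from a dot-bracket structure.

A seeded simulator stands in for the bench: Poisson chain scission with
per-site propensities shaped by base identity (C > G > A ≈ U), structure
context and planted hotspots, ideal RT read-out, and a Gaussian-smeared
electropherogram for the CE integrity metric (% of trace area in the
2100–3300 nt main-peak window).

## Worked example

Call hotspots on the bundled reference construct (a synthetic 2896-nt
GFP-Luc-style mRNA carrying the known degradation-sensitive motifs):

```python
from mprtseq import classify_high_intensity, find_hotspots, reference_bundle

bundle = reference_bundle()
masks = {r: classify_high_intensity(p, bundle.baselines[r])
         for r, p in bundle.profiles.items()}
calls = find_hotspots(masks, sequence=bundle.construct.sequence)
for h in calls:
    print(h.start, h.end, h.sequence)
```

prints the four sequence sets sensitive in both regimes:

```
1986 1988 GCC
2307 2312 CCGACC
2438 2442 UUCGU
2750 2753 UUGG
```

i.e. the GCC/CGACC/UUCGU/UUGG motifs at their annotated coordinates, each
lying on the 5′ strand of a bulge–stem–loop hairpin (see
`examples/05_structure_context.py`). A simulated freeze–thaw ladder
(`examples/02_simulate_stress_ladder.py`, 10⁴ molecules, seed 1) prints

```
cycles  integrity%  avg size (nt)
     0      100.0        2896
     5       96.7        2834
    10       93.6        2778
    20       87.9        2673
```

— CE integrity falls as cuts accumulate while the profile's mean
reactivity rises, the complementary whole-molecule vs per-nucleotide views
of the same degradation.

The `examples/` scripts walk through each capability; `mprtseq all --seed 1
--out run/` runs the whole pipeline from the shell and writes profile TSVs,
hotspot BED/JSON, integrity JSON, figures and a Markdown report, all
embedding the config hash and seed (identical config + seed ⇒ byte-identical
numbers).

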