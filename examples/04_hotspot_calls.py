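"""Call degradation hotspots on the bundled reference profiles.

A position is high intensity when its reactivity exceeds the regime's
rescaled average line IA(N) = A (1+q)^N; runs of high positions shared by
both stress regimes (freeze-thaw and 37 degC heating) become hotspot calls.
The fixture reproduces the four known degradation-sensitive sequence sets.
"""
from mprtseq import classify_high_intensity, find_hotspots, fold_change, reference_bundle

bundle = reference_bundle()
masks = {
    regime: classify_high_intensity(profile, bundle.baselines[regime])
    for regime, profile in bundle.profiles.items()
}
calls = find_hotspots(masks, sequence=bundle.construct.sequence)

print(f"{len(calls)} hotspot calls shared by both regimes:\n")
for i, h in enumerate(calls, 1):
    element = bundle.construct.element_at(h.start)
    folds = {
        regime: fold_change(bundle.profiles[regime], h.start, h.end,
                            bundle.baselines[regime].A)
        for regime in bundle.profiles
    }
    fold_txt = ", ".join(f"{r} {f:.1f}x" for r, f in folds.items())
    print(f"{i}. {h.start}-{h.end}  5'-{h.sequence}-3'  in {element}  ({fold_txt})")
print("\nfold change = window mean / regime average reactivity (A)")
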