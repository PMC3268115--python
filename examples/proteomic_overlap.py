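"""Cross-reference a candidate set with a reference ciliary-proteome list.

A candidate set of 213 proteins of which 157 appear in a 472-protein
reference list (the published marginal counts) splits into detected and
novel parts, with the percentages rendered the way the screen's summary
reports them.
"""

from ciliaprofile import format_percentage, intersect_with_reference, summarize_overlap

candidates = {f"prot{i:04d}" for i in range(213)}
reference = {f"prot{i:04d}" for i in range(157)} | {f"ext{i:04d}" for i in range(315)}

detected, novel = intersect_with_reference(candidates, reference)
print(f"candidates: {len(candidates)}  detected: {len(detected)}  novel: {len(novel)}")

summary = summarize_overlap(candidates, reference, dataset_size=4802)
print(f"set is {summary.pct_of_dataset} of the {summary.dataset_size}-protein dataset;")
print(f"{summary.pct_detected} of it was previously detected in ciliary proteomics,")
print(f"which is {format_percentage(len(detected), 472)} of all 472 proteomically "
      f"detected proteins; {summary.novel} candidates are novel.")
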