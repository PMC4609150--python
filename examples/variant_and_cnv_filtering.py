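"""Somatic-call filtering, CNV classification and mutation patterns.

Walks the genotype layer on tiny hand-made tables: QC-filter somatic
calls, classify copy-number segments, map segments onto gene intervals,
and build the binary mutation pattern that labels the ROC screen.
"""

import pandas as pd

from g2o import (
    build_mutation_pattern,
    classify_cnv_segments,
    filter_somatic_calls,
    map_segments_to_genes,
)

calls = pd.DataFrame(
    {
        "sample_id": ["S1", "S2", "S3", "S4"],
        "gene": ["AKT1", "AKT1", "AKT1", "AKT1"],
        "judgment": ["KEEP", "KEEP", "REJECT", "KEEP"],
        "alt_reads": [12, 3, 40, 4],
        "coverage": [80, 60, 90, 20],
        "function_class": [
            "non-synonymous coding", "stop gain", "splice site", "intron",
        ],
    }
)
kept = filter_somatic_calls(calls)  # KEEP + >=4 alt reads + >=20x coverage
print(f"calls kept: {len(kept)}/{len(calls)} "
      f"(samples {sorted(kept['sample_id'])})")

pattern = build_mutation_pattern(kept, ["S1", "S2", "S3", "S4"], ["AKT1"])
print(f"mutation pattern (all classes): {pattern.labels.tolist()}")
silent = build_mutation_pattern(
    kept, ["S1", "S2", "S3", "S4"], ["AKT1"], class_filter="silent"
)
print(f"mutation pattern (silent only): {silent.labels.tolist()}")

segments = pd.DataFrame(
    {
        "sample_id": ["S1", "S1", "S2"],
        "chrom": ["14", "14", "14"],
        "start": [100_000, 500_000, 100_000],
        "end": [300_000, 600_000, 300_000],
        "n_probes": [25, 8, 40],
        "segment_mean": [0.45, 0.9, -0.35],
    }
)
classified = classify_cnv_segments(segments)  # >=10 probes, |mean| > 0.2
print(f"segments classified: {classified['call'].tolist()} "
      f"(1 dropped for probe count)")

intervals = pd.DataFrame(
    {"gene": ["AKT1"], "chrom": ["14"], "start": [250_000], "end": [280_000]}
)
gene_calls = map_segments_to_genes(classified, intervals)
print("gene-level CNV calls:")
print(gene_calls.to_string(index=False))

# The pattern is the ROC label: S1 and S4 carry retained calls under
# "all classes", only S4's intronic call survives the "silent" preset.
# CNV calls can optionally be merged into the pattern via
# build_mutation_pattern(..., cnv_calls=gene_calls).
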