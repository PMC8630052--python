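"""Attribute labeled peptides to genome bins by unique tryptic peptides.

Builds three synthetic MAGs with 10% shared proteins, plants 6/4/3
bin-unique labeled peptides, and attributes them; peptides shared between
bins are reported separately and never counted. Also applies the
two-unique-peptide protein identification rule to a toy hit list.
"""

from sipquant import (
    PeptideHit,
    attribute_labeled,
    build_index,
    identify_proteins,
    simulate_bins,
)

bins, planted = simulate_bins(planted_unique=(6, 4, 3), seed=7)
index = build_index(bins)  # trypsin, 2 missed cleavages, length 6-50

labeled = [p for b in sorted(planted) for p in planted[b]]
shared = sorted(
    p for p, src in index.sources.items() if len({b for b, _ in src}) > 1
)[:2]
table, shared_out, unassigned = attribute_labeled(index, labeled + shared)
print(table.to_string(index=False))
print(f"shared labeled peptides (counted toward no bin): {len(shared_out)}")
print(f"unassigned labeled peptides: {len(unassigned)}")

hits = [
    PeptideHit("AAAAAK", "p1", "binA", unique=True),
    PeptideHit("CCCCCK", "p1", "binA", unique=True),
    PeptideHit("DDDDDK", "p2", "binA", unique=True),
    PeptideHit("EEEEEK", "p2", "binA", unique=False),
]
proteins = identify_proteins(hits)
print(proteins.to_string(index=False))
print("(a protein needs >= 2 unique peptides to count as identified)")
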