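"""Scoring bins against reference genomes.

Bins are assigned to the genome holding the majority of their aligned base
pairs; completeness is the fraction of that genome the bin covers (genome
bases deduplicated), contamination the fraction of bin bases that did not
align to it. Here the truth table of a simulated community plays the role
of a minimap2 alignment, and one bin is deliberately polluted.
"""

from scafcov import evaluate_bins, simulate_community
from scafcov.simulate import truth_alignments

community = simulate_community(n_genomes=3, genome_length=6000, seed=31, bubble_rate=0.2)

bins = {g: [cid for cid, t in community.truth.items() if t == g]
        for g in community.genomes}
# pollute bin 1 with a foreign contig from genome 3
foreign = bins["genome_003"].pop(0)
bins["genome_001"].append(foreign)

metrics = evaluate_bins(
    bins,
    truth_alignments(community),
    community.contig_lengths(),
    community.genome_lengths(),
)
print(metrics.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# genome_001's bin shows the foreign contig as contamination; genome_003's
# bin lost a contig, so its completeness drops below 100%.
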