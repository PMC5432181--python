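"""Protein-level functional diversity of a VH library.

Translates the consensus of every collapsed cluster: frameshifted
members (length not a multiple of 3) and stop-bearing coding sequences
are filtered out, synonymous nucleotide clusters collapse onto one
protein, and ambiguity at error-flagged codons widens the functional
count into a [conservative, optimistic] range.
"""

import dealkit as dk

cfg = dk.SimulationConfig(
    n_unique=1500, n_reads=6000, construct="vh", coverage="exact",
    frameshift_fraction=0.134, stop_fraction=0.103, rng_seed=9,
    error_spec=dk.ErrorSpec(baseline=0.0, spikes=()),
)
rep = dk.generate_repertoire(cfg)
run = dk.simulate_reads(rep, cfg)
pseudo = []
for idx, (r1s, r2s) in sorted(run.reads_by_index.items()):
    pseudo += dk.preprocess_pairs(r1s, r2s, mode="vh").pseudo_reads
result = dk.run_deal(pseudo, dk.SeedSpec.vh(), profile=dk.ErrorProfile.flat(0.0))

report = dk.protein_clusters(result.clusters)
print(f"nucleotide clusters      : {report.n_nt_clusters}")
print(f"in frame                 : {report.pct_in_frame:.2f}%")
print(f"without stop codon (CDS) : {report.pct_no_stop[0]:.1f}-{report.pct_no_stop[1]:.1f}%")
print(f"full-length CDS          : {report.pct_full_cds[0]:.1f}-{report.pct_full_cds[1]:.1f}%")
print(f"protein clusters         : {report.total_protein_clusters}")
print(f"functional clusters      : {report.functional_clusters[0]}-{report.functional_clusters[1]}")
print(f"minimal (cardinality>=2) : {report.minimal_protein}")
print(f"two-chain projection     : {report.scfv_functional_pct[0]:.1f}-"
      f"{report.scfv_functional_pct[1]:.1f}%  (independence assumption)")
# With no sequencing errors the bounds coincide; flagged ambiguity would
# separate them.
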