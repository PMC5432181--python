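"""Chain assortment: observed primer-pair frequencies vs independence.

Each construct carries one forward (V-class) and one reverse (J-class)
primer scaffold.  Under unbiased library construction the joint class
frequencies factorise into the product of the marginals; a coupled
simulation shows how amplification bias would surface in the log2
observed/expected heatmap.
"""

import numpy as np

import dealkit as dk

lib = dk.default_primer_library()

for coupling, label in ((0.0, "independent"), (0.6, "V-J coupled")):
    cfg = dk.SimulationConfig(
        n_unique=3000, n_reads=3000, construct="scfv", coverage="exact",
        vj_coupling=coupling, rng_seed=11,
        error_spec=dk.ErrorSpec(baseline=0.0, spikes=()),
    )
    rep = dk.generate_repertoire(cfg)
    table = dk.assortment(dk.assign_pairs([s.sequence for s in rep.sequences], lib))
    dev = float(np.nanmax(np.abs(table.log2_ratio.to_numpy())))
    print(f"{label:12s}: classified {table.n_classified}/{table.n_pairs}, "
          f"chi2 = {table.chi2:8.1f}, max |log2(obs/exp)| = {dev:.2f}")
# The independent library stays within multinomial noise (|log2| << 1);
# the coupled one concentrates mass on matched V-J pairs and lights up
# the off-diagonal cells.
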