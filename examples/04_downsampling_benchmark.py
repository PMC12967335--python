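"""Recovery of pseudo-bulk compartments from heavily downsampled data.

Simulates a deep pseudo-bulk matrix with planted compartments, thins it
binomially at single-cell-like rates (1/400 down to 1/3200), and measures
how well the calls on the sparse matrices match the planted labels.
"""

import numpy as np

import schicab as sc

for rate_inv in (400, 800, 1600, 3200):
    vals = []
    for seed in range(3):
        truth = sc.make_truth(n=100, K_true=7, mu_within=4000, mu_between=800,
                              dropout_within=0.0, dropout_between=0.0,
                              noise_sd=50.0, seed=seed)
        bulk = sc.sample_matrix(truth, seed=300 + seed)
        cell = sc.downsample(bulk, rate=1 / rate_inv, seed=700 + seed)
        cpg = sc.CpGTrack(values=truth.binary_bin_labels())
        prof = sc.annotate_cell(cell, cpg, sc.RunConfig(K=7, n_repeats=5, seed=seed),
                                expected=sc.expected_profile(bulk))
        vals.append(sc.intersection(prof.binary_labels(), truth.binary_bin_labels()))
    total = int(cell.values[np.triu_indices(cell.n)].sum())
    print(f"rate 1/{rate_inv:<5d} (~{total} contacts/cell): "
          f"mean intersection {np.mean(vals):.3f}")
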