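"""Paired-difference analysis: isolate the LSC effect from mean intensity.

Orders images by I_mean, differences adjacent neighbors, and correlates
the spike-count differences with the LSC differences.  Because
neighboring images have nearly identical I_mean, any correlation that
survives is a genuine spatial-contrast effect.  Run for both a linear
and a subunit cell to see the contrast.
"""

from rgcsc.image_features import feature_table
from rgcsc.paired import make_pairs, pair_correlations
from rgcsc.synthetic import (SyntheticImageSetSpec, generate_images,
                             make_linear_cell, make_subunit_cell,
                             simulate_flash_responses)

images = generate_images(SyntheticImageSetSpec(n_images=300, seed=9))

for label, cell in [("linear ", make_linear_cell()),
                    ("subunit", make_subunit_cell())]:
    resp = simulate_flash_responses(cell, images, n_trials=10, seed=10)
    feats = feature_table(images, cell.rf)
    pairs = make_pairs(feats, resp.mean_counts)
    corr = pair_correlations(pairs)
    print(f"{label} cell: {len(pairs)} pairs | "
          f"corr(dI_mean, dSpikes) = {corr['r_dimean_dspikes']:+.3f} | "
          f"corr(dLSC, dSpikes) = {corr['r_dlsc_dspikes']:+.3f} | "
          f"slope = {corr['slope_dlsc_dspikes']:+.2f}")
# Expected: ~0 dLSC correlation for the linear cell, clearly positive
# (>0.3) for the subunit cell.  The residual dI_mean correlation is
# negative for these OFF cells (counts fall with raw I_mean) and shrinks
# as the image set grows denser; it is far below the raw count-vs-I_mean
# correlation, which is what the pairing is designed to remove.
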