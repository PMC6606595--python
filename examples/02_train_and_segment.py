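"""Train a model by Baum-Welch and annotate the genome into states.

Trains on synthetic data with known truth, so the recovered emission
parameters and the per-base decoding can be scored against the generating
model.  Subsampled training (a random subset of genome slices per EM
iteration) is what makes whole-genome training tractable; here the dataset
is small enough to use every slice.
"""

import numpy as np

import conshmm as ch

true_model = ch.preset_clade_model(n_species=8, n_states=4)
partition = ch.GenomePartition(chromosomes=(("chr1", 200_000),), slice_length=50_000)
truth = ch.simulate(true_model, partition, seed=11)

init = ch.random_init(true_model.species, n_states=4, seed=42)
fitted = ch.baum_welch(init, truth.obs, n_iterations=100,
                       segments_per_iteration=None, seed=0)

errors = ch.recovery_errors(true_model, fitted)
print(f"max |error| after state matching: f {errors['f']:.4f}, g {errors['g']:.4f}, b {errors['b']:.4f}")

paths = [ch.decode(fitted, obs) for obs in truth.obs]
posts = [ch.forward_backward(fitted, obs) for obs in truth.obs]
seg = ch.merge_segmentation(paths, partition, fitted.n_states)
print(f"{ch.count_segments(seg)} segments over {seg.total_bases:,} bases "
      f"(mean length {seg.total_bases / ch.count_segments(seg):.0f} b)")

conf = ch.posterior_confidence(posts, paths, fitted.n_states)
print("per-state mean assigned posterior:", np.round(conf, 3))
# Values near 1 mean the model is confident in its per-base assignments.

print(f"BIC of the fitted model: {ch.bic(fitted, truth.obs):,.0f}")
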