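"""Simulate an alignment with known truth and encode it back into observations.

The clade preset defines states that align and match progressively smaller
subsets of species.  The emitted MAF text, when parsed and encoded, must
reproduce the simulated per-base observations exactly - that round trip is
the foundation every downstream stage builds on.
"""

import io

import conshmm as ch

model = ch.preset_clade_model(n_species=8, n_states=4)
partition = ch.GenomePartition(chromosomes=(("chr1", 50_000),), slice_length=20_000)
truth = ch.simulate(model, partition, seed=7)
maf_text = ch.emit_maf(truth, nucleotide_seed=8)

blocks = list(ch.parse_maf(io.StringIO(maf_text), model.species))
print(f"simulated {partition.total_bases} bases for {model.species.n_species} species")
print(f"MAF text: {len(maf_text):,} characters in {len(blocks)} blocks")

exact = True
aligned = matched = 0
for (chrom, start, end), obs in zip(partition.slices, truth.obs):
    encoded = ch.encode_observations(blocks, model.species, chrom, start, end)
    exact &= encoded == obs
    aligned += int((obs.y == 1).sum())
    matched += int(((obs.y == 1) & (obs.z == 1)).sum())

cells = partition.total_bases * model.species.n_others
print(f"round trip exact: {exact}")
print(f"aligned cells: {aligned / cells:.1%} of {cells:,}; matching among aligned: {matched / aligned:.1%}")
# The two percentages are the genome-wide averages of the per-state align
# probability f and conditional match probability g, mixed over states.
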