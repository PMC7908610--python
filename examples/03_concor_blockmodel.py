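"""CONCOR blockmodel of the synthetic network.

Partitions provinces into up to four structurally equivalent blocks,
prints the block spillover accounting (internal vs external relations,
expected vs actual internal share, and the four-way role labels) and the
inter-block density/image matrices.
"""

from healthnet import (
    binarize,
    block_density_image,
    block_spillover_table,
    concor_partition,
    generate_distances,
    generate_provinces,
    gravity_matrix,
)

table = generate_provinces(31, "core_periphery", seed=1)
A = binarize(gravity_matrix(table, generate_distances(table, seed=1)))

part = concor_partition(A, depth=2, criterion=0.2)
print("block sizes:", part.block_sizes())

spill = block_spillover_table(A, part)
print("\nblock spillover accounting (% ratios of internal relations):")
print(spill.round(3).to_string(index=False))

di = block_density_image(A, part)
print(f"\ninter-block densities (cutoff = network density {di.cutoff:.4f}):")
print(di.density_frame().round(3).to_string())
print("\nimage matrix (1 = denser than the whole network):")
print(di.image_frame().to_string())
print(f"\nblockmodel fit R^2 = {di.fit_r2:.3f} "
      "(how much of the arc pattern the block densities explain)")
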