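"""Reconstruct the founder haplotype structure from the packaged
carrier table: shared core, founder extension, recombination blocks."""

from founderage import (
    find_shared_core,
    infer_founder,
    partition_blocks,
    table1_fixture,
)

marker_map, matrix = table1_fixture()
print(f"{matrix.n_chromosomes} carrier chromosomes × {len(marker_map)} markers")

core = find_shared_core(matrix, marker_map)
print(
    f"shared autozygous core: {marker_map.rsids[core.start]}..."
    f"{marker_map.rsids[core.stop - 1]} ({len(core)} markers)"
)
# Every carrier chromosome is identical over this run: the footprint of
# the haplotype on which the mutation arose.

founder = infer_founder(matrix, marker_map, core)
partition = partition_blocks(matrix, marker_map, founder)
print(f"\n{'block':>16} {'markers':>7} {'theta':>8} {'sharing':>7}")
for b in partition.blocks:
    print(
        f"{b.label_rsid:>16} {b.n_markers:>7} {b.theta:>8.5f} "
        f"{b.shared_chromosomes:>7}"
    )
print("unassigned tail markers:", [marker_map.rsids[i] for i in partition.tail_indices])
# theta is the recombination fraction from the mutation to the block
# (1 Mb = 1 cM); "sharing" counts chromosomes that conserve the founder
# haplotype from the mutation out through the block — the decay of this
# count with distance is the clock the age estimators read.
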