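import numpy as np
import pytest

from founderage import (
    CarrierMatrix,
    MarkerMap,
    Marker,
    find_shared_core,
    infer_founder,
    partition_blocks,
    table1_fixture,
    table2_inputs,
)


@pytest.fixture(scope="session")
def study():
    """Packaged carrier table parsed once per session."""
    marker_map, matrix = table1_fixture()
    return marker_map, matrix


@pytest.fixture(scope="session")
def study_founder(study):
    marker_map, matrix = study
    core = find_shared_core(matrix, marker_map)
    founder = infer_founder(matrix, marker_map, core)
    return core, founder


@pytest.fixture(scope="session")
def study_partition(study, study_founder):
    marker_map, matrix = study
    _, founder = study_founder
    return partition_blocks(matrix, marker_map, founder)


@pytest.fixture(scope="session")
def block_inputs():
    return table2_inputs()


def make_map(positions, focal_pos, cm_per_mb=1.0):
    markers = [Marker(rsid=f"m{i}", pos_bp=p) for i, p in enumerate(positions)]
    return MarkerMap(
        markers=markers,
        focal_index=list(positions).index(focal_pos),
        cm_per_mb=cm_per_mb,
    )


def make_matrix(haplotypes: dict[str, str]) -> CarrierMatrix:
    """Build a carrier matrix from family -> allele-string, two identical
    chromosomes per family."""
    labels, rows = [], []
    for fam, hap in haplotypes.items():
        for suffix in ("a", "b"):
            labels.append(f"{fam}-{suffix}")
            rows.append(list(hap))
    return CarrierMatrix(
        chromosome_labels=labels, alleles=np.array(rows, dtype="<U1")
    )
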