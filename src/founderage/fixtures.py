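"""Packaged study data.

Two machine-readable tables ship with the package:

* the carrier-haplotype marker table (98 flanking SNPs plus the focal
  CLCC1 c.75C>A site at chr1:108,950,376, GRCh38, across 18 carrier
  chromosomes from 9 autozygous families), and
* the per-block age-estimation inputs (sharing counts, control
  haplotype frequencies Fn estimated by EM/CHM from a South-Asian
  reference panel, recombination fraction theta, block sizes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .markers import CarrierMatrix, MarkerMap, parse_marker_table

_DATA = resources.files("founderage") / "data"


def table1_fixture(cm_per_mb: float = 1.0) -> tuple[MarkerMap, CarrierMatrix]:
    """The packaged carrier-haplotype table: 99 marker rows (focal
    mutation row included) × 18 carrier chromosomes, ``-`` as missing."""
    with resources.as_file(_DATA / "table1_carriers.tsv") as path:
        return parse_marker_table(path, cm_per_mb=cm_per_mb)


def table2_inputs() -> pd.DataFrame:
    """Per-block age-estimation inputs, one row per haplotype block in
    genomic order of the block label markers.

    Columns: ``label_rsid``, ``shared_chromosomes``, ``fn_em``,
    ``fn_chm`` (control-panel frequencies of the founder block
    haplotype), ``theta`` (printed, rounded recombination fraction),
    ``n_snps``, ``pr_em``, ``pr_chm``.
    """
    with resources.as_file(_DATA / "table2_blocks.tsv") as path:
        return pd.read_csv(path, sep="\t")
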