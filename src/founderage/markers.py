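"""Marker maps and carrier haplotype matrices.

The coordinate backbone of the analysis is an ordered list of SNP markers
on one chromosome plus the index of the focal (disease) mutation site.
Genetic distances are derived from physical distances with a constant
cM/Mb conversion (default 1 cM per Mb), so the recombination fraction
between the focal site and a marker is ``|Δbp| * cm_per_mb * 1e-8``.

Carrier chromosomes are stored as an alleles matrix over {A, C, G, T}
with ``-`` for missing genotypes.  Chromosome labels follow the
``<family>-<a|b>`` convention; the two chromosomes of an autozygous
carrier are expected to be identical wherever both are genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "-"
ALLELES = frozenset({"A", "C", "G", "T"})
#: reserved rsid token identifying the focal mutation row in marker tables
FOCAL_TOKEN = "CLCC1-MUTATION"


class ParseError(ValueError):
    """Raised when a marker table violates the expected format."""


@dataclass(frozen=True)
class Marker:
    rsid: str
    pos_bp: int
    chrom: str = "1"


@dataclass
class MarkerMap:
    """Ordered markers with a physical→genetic distance rule.

    Parameters
    ----------
    markers
        Markers sorted by strictly increasing position (1-based bp).
    focal_index
        Index of the focal mutation site within ``markers``.
    cm_per_mb
        Constant map conversion rate; 1.0 means 1 Mb ≡ 1 cM.
    """

    markers: list[Marker]
    focal_index: int
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        pos = self.positions
        if len(self.markers) == 0:
            raise ValueError("marker map is empty")
        if not (0 <= self.focal_index < len(self.markers)):
            raise ValueError(f"focal_index {self.focal_index} out of range")
        if np.any(np.diff(pos) <= 0):
            i = int(np.argmax(np.diff(pos) <= 0)) + 1
            raise ParseError(
                f"positions not strictly increasing at row {i} "
                f"({self.markers[i].rsid})"
            )
        rsids = self.rsids
        if len(set(rsids)) != len(rsids):
            dup = pd.Series(rsids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ParseError(f"duplicate rsid {dup!r}")

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos_bp for m in self.markers], dtype=np.int64)

    @property
    def rsids(self) -> list[str]:
        return [m.rsid for m in self.markers]

    @property
    def focal(self) -> Marker:
        return self.markers[self.focal_index]

    def __len__(self) -> int:
        return len(self.markers)

    def index_of(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"marker {rsid!r} not in map") from None

    def genetic_distance(self, i: int, j: int) -> float:
        """Distance between markers i and j in centimorgans."""
        return abs(int(self.markers[i].pos_bp) - int(self.markers[j].pos_bp)) * (
            self.cm_per_mb * 1e-6
        )

    def theta(self, i: int, j: int | None = None) -> float:
        """Recombination fraction (unitless, cM/100) between marker ``i``
        and marker ``j`` (the focal site when ``j`` is omitted)."""
        j = self.focal_index if j is None else j
        return self.genetic_distance(i, j) / 100.0

    def morgans_from_focal(self, pos_bp: float) -> float:
        """Genetic distance in Morgans from the focal site to a physical
        position (which need not be a marker position)."""
        return abs(float(pos_bp) - self.focal.pos_bp) * self.cm_per_mb * 1e-8


@dataclass
class CarrierMatrix:
    """Carrier-chromosome × marker allele matrix.

    ``alleles[k, i]`` is the allele of chromosome ``k`` at marker ``i``;
    ``-`` marks a missing genotype, which downstream analyses treat as
    compatible with any allele.
    """

    chromosome_labels: list[str]
    alleles: np.ndarray  # dtype '<U1', shape (n_chromosomes, n_markers)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != len(self.chromosome_labels):
            raise ValueError("one label required per chromosome row")
        bad = ~np.isin(self.alleles, list(ALLELES | {MISSING}))
        if bad.any():
            k, i = map(int, np.argwhere(bad)[0])
            raise ParseError(
                f"allele {self.alleles[k, i]!r} outside alphabet at "
                f"chromosome {self.chromosome_labels[k]}, marker column {i}"
            )

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def family_of(self, label: str) -> str:
        return label.rsplit("-", 1)[0]

    @property
    def families(self) -> dict[str, list[int]]:
        """Family id → row indices, preserving first-seen order."""
        fams: dict[str, list[int]] = {}
        for k, lab in enumerate(self.chromosome_labels):
            fams.setdefault(self.family_of(lab), []).append(k)
        return fams

    def validate_focal(self, marker_map: MarkerMap) -> None:
        """Every carrier chromosome must carry the (non-missing) risk
        allele at the focal site."""
        col = self.alleles[:, marker_map.focal_index]
        if (col == MISSING).any():
            k = int(np.argmax(col == MISSING))
            raise ParseError(
                f"missing focal genotype on {self.chromosome_labels[k]}"
            )
        if len(set(col)) != 1:
            raise ParseError("carrier chromosomes disagree at the focal site")


def parse_marker_table(
    path: str | Path,
    focal_rsid: str = FOCAL_TOKEN,
    cm_per_mb: float = 1.0,
) -> tuple[MarkerMap, CarrierMatrix]:
    """Read a tab-separated marker table into a map and carrier matrix.

    Expected layout: header ``pos  rsid  <label> ...`` with one column per
    carrier chromosome; rows sorted by position; alleles in {A,C,G,T,-};
    the focal mutation row identified by the reserved rsid ``focal_rsid``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["pos", "rsid"]:
        raise ParseError(
            f"{path}: expected header 'pos<TAB>rsid<TAB><chromosome labels...>'"
        )
    try:
        positions = df["pos"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position ({exc})") from exc
    rsids = df["rsid"].astype(str).tolist()
    if focal_rsid not in rsids:
        raise ParseError(f"{path}: focal row {focal_rsid!r} not found")
    markers = [Marker(rsid=r, pos_bp=int(p)) for r, p in zip(rsids, positions)]
    marker_map = MarkerMap(
        markers=markers, focal_index=rsids.index(focal_rsid), cm_per_mb=cm_per_mb
    )
    labels = list(df.columns[2:])
    alleles = df[labels].fillna(MISSING).to_numpy(dtype="<U1").T
    matrix = CarrierMatrix(chromosome_labels=labels, alleles=alleles)
    matrix.validate_focal(marker_map)
    return marker_map, matrix


def write_marker_table(
    path: str | Path, marker_map: MarkerMap, matrix: CarrierMatrix
) -> None:
    """Serialize a map + carrier matrix back to the TSV layout accepted by
    :func:`parse_marker_table` (round-trip safe)."""
    if len(marker_map) != matrix.n_markers:
        raise ValueError("map and matrix disagree on marker count")
    df = pd.DataFrame(
        {"pos": marker_map.positions, "rsid": marker_map.rsids}
    )
    for k, lab in enumerate(matrix.chromosome_labels):
        df[lab] = matrix.alleles[k]
    df.to_csv(path, sep="\t", index=False)
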