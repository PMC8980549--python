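"""Ancestral haplotype reconstruction and recombination-block structure.

Given carrier chromosomes all bearing one focal mutation, this module

* finds the fully shared (autozygous) core around the mutation,
* reconstructs the founder haplotype by outward maximal-sharing
  extension,
* partitions markers into recombination-free blocks with a
  recombination fraction (theta) from each block to the mutation,
* derives per-family recombination events and shared-recombinant
  ancestor groups, and
* measures conserved ancestral segment lengths for segment-based
  dating.

Missing genotypes (``-``) are treated as compatible with any allele
throughout: a chromosome with a missing call neither votes for a founder
allele nor is deactivated by one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MISSING, CarrierMatrix, MarkerMap

UNKNOWN = "N"


def _matches(allele: str, founder_allele: str) -> bool:
    """Missing-tolerant allele comparison; UNKNOWN founder matches all."""
    return (
        allele == MISSING
        or founder_allele in (UNKNOWN, MISSING)
        or allele == founder_allele
    )


# ---------------------------------------------------------------------------
# family collapsing


@dataclass
class FamilyHaplotypes:
    """Carrier families collapsed to one haplotype each.

    All affected individuals are autozygous, so the two chromosomes of a
    family should be identical; positions where both are genotyped but
    disagree are recorded in ``discordances`` as (family, marker index)
    and resolved to the first chromosome's allele.
    """

    family_ids: list[str]
    alleles: np.ndarray  # (n_families, n_markers)
    n_chromosomes: dict[str, int]
    discordances: list[tuple[str, int]] = field(default_factory=list)


def collapse_families(matrix: CarrierMatrix) -> FamilyHaplotypes:
    fams = matrix.families
    ids, rows, sizes, disc = [], [], {}, []
    for fam, members in fams.items():
        block = matrix.alleles[members]
        hap = np.full(matrix.n_markers, MISSING, dtype="<U1")
        for i in range(matrix.n_markers):
            seen = [a for a in block[:, i] if a != MISSING]
            if seen:
                hap[i] = seen[0]
                if len(set(seen)) > 1:
                    disc.append((fam, i))
        ids.append(fam)
        rows.append(hap)
        sizes[fam] = len(members)
    return FamilyHaplotypes(
        family_ids=ids,
        alleles=np.array(rows, dtype="<U1"),
        n_chromosomes=sizes,
        discordances=disc,
    )


def _duplicate_classes(fams: FamilyHaplotypes) -> dict[str, int]:
    """Partition families into classes of (missing-tolerant) identical
    haplotypes.  Identical haplotypes most plausibly share post-founder
    ancestry and are down-weighted to one lineage when breaking founder
    extension ties."""
    class_of: dict[str, int] = {}
    reps: list[np.ndarray] = []
    for fam, hap in zip(fams.family_ids, fams.alleles):
        for ci, rep in enumerate(reps):
            both = (hap != MISSING) & (rep != MISSING)
            if np.all(hap[both] == rep[both]):
                class_of[fam] = ci
                break
        else:
            class_of[fam] = len(reps)
            reps.append(hap)
    return class_of


# ---------------------------------------------------------------------------
# shared core


def find_shared_core(matrix: CarrierMatrix, marker_map: MarkerMap) -> range:
    """Maximal contiguous marker run containing the focal site on which
    all chromosomes' non-missing alleles are identical.

    Returns a ``range`` of marker indices.  The run always contains at
    least the focal site itself.
    """
    if matrix.n_chromosomes == 0:
        raise ValueError("carrier matrix is empty")
    n = matrix.n_markers

    def column_consistent(i: int) -> bool:
        seen = {a for a in matrix.alleles[:, i] if a != MISSING}
        return len(seen) <= 1

    lo = hi = marker_map.focal_index
    while lo - 1 >= 0 and column_consistent(lo - 1):
        lo -= 1
    while hi + 1 < n and column_consistent(hi + 1):
        hi += 1
    return range(lo, hi + 1)


# ---------------------------------------------------------------------------
# founder inference


@dataclass
class FounderHaplotype:
    """Inferred ancestral haplotype with per-marker support.

    ``support[i]`` counts carrier chromosomes still consistent with the
    founder at marker ``i`` under the outward-extension rule (equal to
    the total count throughout the shared core, non-increasing moving
    outward).  ``alleles[i]`` may be ``N`` where no active chromosome
    was genotyped.  Markers where the plurality vote was broken by the
    deterministic fallback order are listed in ``tie_indices``.
    """

    alleles: list[str]
    support: np.ndarray
    core: range
    tie_indices: list[int] = field(default_factory=list)

    def allele(self, i: int) -> str:
        return self.alleles[i]


def _lookahead_score(
    fams: FamilyHaplotypes,
    active: list[int],
    weights: np.ndarray,
    order: list[int],
) -> float:
    """Greedy continuation score: total chromosome-marker agreement with
    a plurality-extended founder over the remaining outward markers."""
    total = 0.0
    active = list(active)
    for i in order:
        votes: dict[str, float] = {}
        for f in active:
            a = fams.alleles[f, i]
            if a != MISSING:
                votes[a] = votes.get(a, 0.0) + weights[f]
        if votes:
            best = max(sorted(votes), key=lambda a: votes[a])
            active = [
                f
                for f in active
                if fams.alleles[f, i] in (MISSING, best)
            ]
        total += sum(weights[f] for f in active)
    return total


def infer_founder(
    matrix: CarrierMatrix,
    marker_map: MarkerMap,
    core: range | None = None,
) -> FounderHaplotype:
    """Reconstruct the founder haplotype by outward maximal-sharing
    extension from the shared core.

    Within the core the founder carries the shared allele.  Moving
    outward one marker at a time on each side, the founder allele is the
    plurality allele among chromosomes still consistent with the founder
    on that side; mismatching chromosomes become inactive for all
    farther markers.  Vote ties are broken in order by (1) plurality
    over distinct family lineages, counting identical family haplotypes
    once, (2) greedy look-ahead parsimony (largest total remaining
    agreement), (3) deterministic lexicographic allele order, recorded
    in ``tie_indices``.
    """
    if core is None:
        core = find_shared_core(matrix, marker_map)
    fams = collapse_families(matrix)
    dup_class = _duplicate_classes(fams)
    n = matrix.n_markers
    n_chrom = matrix.n_chromosomes
    weights = np.array(
        [fams.n_chromosomes[f] for f in fams.family_ids], dtype=float
    )
    alleles = [UNKNOWN] * n
    support = np.zeros(n, dtype=int)
    tie_indices: list[int] = []

    for i in core:
        seen = {a for a in matrix.alleles[:, i] if a != MISSING}
        alleles[i] = seen.pop() if seen else UNKNOWN
        support[i] = n_chrom

    for direction in (-1, +1):
        if direction < 0:
            order = list(range(core.start - 1, -1, -1))
        else:
            order = list(range(core.stop, n))
        active = list(range(len(fams.family_ids)))
        for pos, i in enumerate(order):
            votes: dict[str, float] = {}
            lineages: dict[str, set[int]] = {}
            for f in active:
                a = fams.alleles[f, i]
                if a != MISSING:
                    votes[a] = votes.get(a, 0.0) + weights[f]
                    lineages.setdefault(a, set()).add(
                        dup_class[fams.family_ids[f]]
                    )
            if not votes:
                alleles[i] = UNKNOWN
                support[i] = int(sum(weights[f] for f in active))
                continue
            top = max(votes.values())
            tied = sorted(a for a, v in votes.items() if v == top)
            if len(tied) > 1:
                tie_indices.append(i)
            if len(tied) > 1:
                top_lin = max(len(lineages[a]) for a in tied)
                tied = [a for a in tied if len(lineages[a]) == top_lin]
            if len(tied) > 1:
                rest = order[pos + 1 :]
                scores = {}
                for a in tied:
                    surv = [
                        f
                        for f in active
                        if fams.alleles[f, i] in (MISSING, a)
                    ]
                    scores[a] = _lookahead_score(fams, surv, weights, rest)
                top_score = max(scores.values())
                tied = [a for a in tied if scores[a] == top_score]
            # remaining ties fall through to lexicographic order (tied is
            # sorted); the marker is already flagged in tie_indices
            chosen = tied[0]
            alleles[i] = chosen
            active = [
                f for f in active if fams.alleles[f, i] in (MISSING, chosen)
            ]
            support[i] = int(sum(weights[f] for f in active))

    return FounderHaplotype(
        alleles=alleles,
        support=support,
        core=core,
        tie_indices=sorted(tie_indices),
    )


# ---------------------------------------------------------------------------
# block partition


@dataclass
class Block:
    """A run of contiguous markers with no internal recombination
    boundary among founder-consistent carriers."""

    label_rsid: str
    label_index: int
    start: int  # inclusive marker index
    stop: int  # inclusive marker index
    theta: float
    shared_chromosomes: int = 0
    is_focal: bool = False
    is_distal: bool = False  # detached two-marker block at the outermost
    # divergence (basis of two-marker estimators)

    @property
    def n_markers(self) -> int:
        return self.stop - self.start + 1

    @property
    def member_markers(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass
class BlockPartition:
    blocks: list[Block]  # ordered by genomic position
    tail_indices: list[int]

    @property
    def focal_block(self) -> Block:
        return next(b for b in self.blocks if b.is_focal)

    def by_label(self, rsid: str) -> Block:
        try:
            return next(b for b in self.blocks if b.label_rsid == rsid)
        except StopIteration:
            raise KeyError(f"no block labeled {rsid!r}") from None


def _family_divergence(
    fams: FamilyHaplotypes, founder: FounderHaplotype, n: int
) -> dict[str, dict[int, int | None]]:
    """First non-missing founder-mismatch marker index per family per
    side (-1 left / +1 right), or None if consistent to the map end."""
    core = founder.core
    out: dict[str, dict[int, int | None]] = {}
    for fam, hap in zip(fams.family_ids, fams.alleles):
        div: dict[int, int | None] = {-1: None, +1: None}
        for i in range(core.start - 1, -1, -1):
            if not _matches(hap[i], founder.alleles[i]):
                div[-1] = i
                break
        for i in range(core.stop, n):
            if not _matches(hap[i], founder.alleles[i]):
                div[+1] = i
                break
        out[fam] = div
    return out


def partition_blocks(
    matrix: CarrierMatrix,
    marker_map: MarkerMap,
    founder: FounderHaplotype,
) -> BlockPartition:
    """Partition markers into recombination-free blocks.

    A boundary is placed wherever the set of founder-consistent
    chromosomes changes, i.e. at each family's divergence marker; each
    block is labeled by its member marker nearest the focal site.  The
    blocking on each side stops once only two families retain the
    founder haplotype: if the two survivors agree with the founder to
    the map end, the final divergence opens a terminal block running to
    the end; otherwise the terminating divergence marker closes the
    current block, a detached two-marker block is placed at the
    outermost remaining divergence (for use with two-marker estimators)
    and the leftover markers are reported unassigned in
    ``tail_indices``.
    """
    fams = collapse_families(matrix)
    n = matrix.n_markers
    core = founder.core
    div = _family_divergence(fams, founder, n)

    blocks: list[Block] = []
    tail: list[int] = []
    focal_lo, focal_hi = core.start, core.stop - 1

    for direction in (-1, +1):
        order = (
            list(range(core.start - 1, -1, -1))
            if direction < 0
            else list(range(core.stop, n))
        )
        if not order:
            continue
        active = set(fams.family_ids)
        div_at: dict[int, list[str]] = {}
        for fam in fams.family_ids:
            d = div[fam][direction]
            if d is not None:
                div_at.setdefault(d, []).append(fam)
        cur_open: int | None = None
        stopped = False
        side_blocks: list[tuple[int, int]] = []  # (open marker, close marker)
        for pos, i in enumerate(order):
            divs = [f for f in div_at.get(i, []) if f in active]
            if divs:
                remaining = active - set(divs)
                to_end = all(div[f][direction] is None for f in remaining)
                if len(remaining) >= 3 or (len(remaining) == 2 and to_end):
                    if cur_open is not None:
                        side_blocks.append((cur_open, order[pos - 1]))
                    else:
                        # markers before the first divergence extend the
                        # focal block
                        if pos > 0:
                            if direction < 0:
                                focal_lo = order[pos - 1]
                            else:
                                focal_hi = order[pos - 1]
                    cur_open = i
                    active = remaining
                else:
                    # terminal divergence: absorb into the current block
                    if cur_open is not None:
                        side_blocks.append((cur_open, i))
                    else:
                        if direction < 0:
                            focal_lo = i
                        else:
                            focal_hi = i
                    cur_open = None
                    active = remaining
                    stopped = True
                    remainder = order[pos + 1 :]
                    if len(remaining) >= 2:
                        outer = [
                            div[f][direction]
                            for f in remaining
                            if div[f][direction] is not None
                        ]
                        if outer:
                            far = (
                                min(outer) if direction < 0 else max(outer)
                            )
                            nxt = far + direction
                            pair = (far, nxt) if direction > 0 else (nxt, far)
                            lo = max(min(pair), 0)
                            hi = min(max(pair), n - 1)
                            blocks.append(
                                Block(
                                    label_rsid=marker_map.rsids[far],
                                    label_index=far,
                                    start=lo,
                                    stop=hi,
                                    theta=marker_map.theta(far),
                                    is_distal=True,
                                )
                            )
                            tail.extend(
                                j
                                for j in remainder
                                if not (lo <= j <= hi)
                            )
                        else:
                            tail.extend(remainder)
                    else:
                        tail.extend(remainder)
                    break
        if not stopped:
            if cur_open is not None:
                side_blocks.append((cur_open, order[-1]))
            else:
                if direction < 0:
                    focal_lo = order[-1]
                else:
                    focal_hi = order[-1]
        for open_i, close_i in side_blocks:
            lo, hi = min(open_i, close_i), max(open_i, close_i)
            blocks.append(
                Block(
                    label_rsid=marker_map.rsids[open_i],
                    label_index=open_i,
                    start=lo,
                    stop=hi,
                    theta=marker_map.theta(open_i),
                )
            )

    blocks.append(
        Block(
            label_rsid=marker_map.focal.rsid,
            label_index=marker_map.focal_index,
            start=focal_lo,
            stop=focal_hi,
            theta=0.0,
            is_focal=True,
        )
    )
    blocks.sort(key=lambda b: b.start)
    partition = BlockPartition(blocks=blocks, tail_indices=sorted(tail))
    _fill_sharing(matrix, founder, partition, marker_map)
    return partition


def _conserved_through(
    matrix: CarrierMatrix, founder: FounderHaplotype, marker_map: MarkerMap, i: int
) -> int:
    """Chromosomes whose haplotype matches the founder at every marker
    between the focal site and marker ``i`` inclusive."""
    lo, hi = sorted((marker_map.focal_index, i))
    count = 0
    for k in range(matrix.n_chromosomes):
        row = matrix.alleles[k, lo : hi + 1]
        if all(
            _matches(a, f)
            for a, f in zip(row, founder.alleles[lo : hi + 1])
        ):
            count += 1
    return count


def _fill_sharing(
    matrix: CarrierMatrix,
    founder: FounderHaplotype,
    partition: BlockPartition,
    marker_map: MarkerMap,
) -> None:
    for b in partition.blocks:
        b.shared_chromosomes = _conserved_through(
            matrix, founder, marker_map, b.label_index
        )


def sharing_counts(
    matrix: CarrierMatrix,
    founder: FounderHaplotype,
    partition: BlockPartition,
    marker_map: MarkerMap,
) -> list[int]:
    """Per-block counts of chromosomes conserving the founder haplotype
    from the mutation through the block's label marker, in block order.

    Counts equal the total chromosome count at the focal block and are
    non-increasing with distance from it on each side.
    """
    return [
        _conserved_through(matrix, founder, marker_map, b.label_index)
        for b in partition.blocks
    ]


def block_theta(block: Block, marker_map: MarkerMap) -> float:
    """Recombination fraction from the focal site to the block's label
    marker (physical distance × cM/Mb × 1e-8; unitless)."""
    return marker_map.theta(block.label_index)


# ---------------------------------------------------------------------------
# per-family recombination events


@dataclass
class FamilyDerivation:
    family_id: str
    left_breakpoint: tuple[int, int] | None  # flanking marker indices
    right_breakpoint: tuple[int, int] | None
    n_events: int
    level: int
    shared_ancestor_group: str | None = None
    data_errors: list[str] = field(default_factory=list)


def derive_family_events(
    matrix: CarrierMatrix,
    founder: FounderHaplotype,
    marker_map: MarkerMap,
) -> list[FamilyDerivation]:
    """Derive each family's recombination events relative to the founder.

    The two chromosomes of a family are collapsed to one haplotype
    (within-family discordances are reported in ``data_errors``).  The
    left/right breakpoints are the outermost marker intervals where the
    family haplotype stops matching the founder; ``n_events`` counts
    non-None breakpoints (the family's level in the descent diagram).
    Families diverging at the same marker with identical recombined-in
    alleles across the remainder of that marker's block are assigned a
    common ``shared_ancestor_group``.
    """
    fams = collapse_families(matrix)
    n = matrix.n_markers
    focal = marker_map.focal_index
    for fam, hap in zip(fams.family_ids, fams.alleles):
        if not _matches(hap[focal], founder.alleles[focal]):
            raise ValueError(
                f"family {fam} does not carry the founder allele at the "
                "focal site"
            )
    div = _family_divergence(fams, founder, n)
    partition = partition_blocks(matrix, marker_map, founder)

    def containing_block(i: int) -> Block | None:
        for b in partition.blocks:
            if b.start <= i <= b.stop:
                return b
        return None

    # group families sharing a divergence event on either side
    parent = {f: f for f in fams.family_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    hap_of = dict(zip(fams.family_ids, fams.alleles))
    for direction in (-1, +1):
        by_marker: dict[int, list[str]] = {}
        for fam in fams.family_ids:
            d = div[fam][direction]
            if d is not None:
                by_marker.setdefault(d, []).append(fam)
        for i, members in by_marker.items():
            if len(members) < 2:
                continue
            blk = containing_block(i)
            if blk is not None:
                span = (
                    range(blk.start, i + 1)
                    if direction < 0
                    else range(i, blk.stop + 1)
                )
            else:
                span = range(i, i + 1)
            for a in members[1:]:
                ha, hb = hap_of[a], hap_of[members[0]]
                same = all(
                    ha[j] == MISSING
                    or hb[j] == MISSING
                    or ha[j] == hb[j]
                    for j in span
                )
                if same:
                    union(a, members[0])

    groups: dict[str, list[str]] = {}
    for fam in fams.family_ids:
        groups.setdefault(find(fam), []).append(fam)
    group_id: dict[str, str] = {}
    counter = 1
    for root in sorted(groups, key=lambda r: fams.family_ids.index(r)):
        members = groups[root]
        if len(members) > 1:
            gid = f"G{counter}"
            counter += 1
            for fam in members:
                group_id[fam] = gid

    disc_by_fam: dict[str, list[str]] = {}
    for fam, i in fams.discordances:
        disc_by_fam.setdefault(fam, []).append(marker_map.rsids[i])

    out = []
    for fam in fams.family_ids:
        l, r = div[fam][-1], div[fam][+1]
        n_events = (l is not None) + (r is not None)
        out.append(
            FamilyDerivation(
                family_id=fam,
                left_breakpoint=None if l is None else (l, l + 1),
                right_breakpoint=None if r is None else (r - 1, r),
                n_events=n_events,
                level=n_events,
                shared_ancestor_group=group_id.get(fam),
                data_errors=disc_by_fam.get(fam, []),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ancestral segment lengths


@dataclass
class SegmentData:
    """One-sided conserved ancestral segment lengths around the focal
    site, in Morgans, for segment-length (Gamma) dating.

    ``lengths`` holds 2n entries (left then right per chromosome);
    ``censored`` flags segments with no observed recombination endpoint
    inside the genotyped map.  ``families``/``groups`` carry lineage
    structure for the correlated-genealogy correction.
    """

    chromosome_labels: list[str]
    left: np.ndarray
    right: np.ndarray
    left_censored: np.ndarray
    right_censored: np.ndarray
    families: list[str]
    left_group: list[str | None]
    right_group: list[str | None]

    @property
    def n(self) -> int:
        return len(self.chromosome_labels)

    @property
    def lengths(self) -> np.ndarray:
        return np.concatenate([self.left, self.right])

    @property
    def censored(self) -> np.ndarray:
        return np.concatenate([self.left_censored, self.right_censored])


CENSORING_CONVENTIONS = ("midpoint", "last-match", "first-mismatch")


def segment_lengths(
    matrix: CarrierMatrix,
    founder: FounderHaplotype,
    marker_map: MarkerMap,
    censoring: str = "midpoint",
) -> SegmentData:
    """Per-chromosome genetic distance from the focal site to the
    estimated recombination point on each side.

    The recombination point is placed at the midpoint between the last
    founder-matching marker and the first discordant marker (``midpoint``
    convention; ``last-match``/``first-mismatch`` place it on either
    flanking marker instead).  Chromosomes with no discordant marker
    before the map end are censored at their outermost genotyped marker.
    """
    if censoring not in CENSORING_CONVENTIONS:
        raise ValueError(
            f"censoring must be one of {CENSORING_CONVENTIONS}, got "
            f"{censoring!r}"
        )
    n = matrix.n_markers
    focal = marker_map.focal_index
    pos = marker_map.positions
    derivs = derive_family_events(matrix, founder, marker_map)
    fam_group = {
        d.family_id: (
            d.shared_ancestor_group if d.left_breakpoint is not None else None,
            d.shared_ancestor_group if d.right_breakpoint is not None else None,
        )
        for d in derivs
    }

    left = np.zeros(matrix.n_chromosomes)
    right = np.zeros(matrix.n_chromosomes)
    lcen = np.zeros(matrix.n_chromosomes, dtype=bool)
    rcen = np.zeros(matrix.n_chromosomes, dtype=bool)
    families = [matrix.family_of(lab) for lab in matrix.chromosome_labels]

    for k in range(matrix.n_chromosomes):
        row = matrix.alleles[k]
        for direction, store, cen in (
            (-1, left, lcen),
            (+1, right, rcen),
        ):
            order = (
                range(focal - 1, -1, -1) if direction < 0 else range(focal + 1, n)
            )
            d = None
            for i in order:
                if not _matches(row[i], founder.alleles[i]):
                    d = i
                    break
            if d is None:
                genotyped = [i for i in order if row[i] != MISSING]
                edge = genotyped[-1] if genotyped else focal
                store[k] = marker_map.morgans_from_focal(pos[edge])
                cen[k] = True
            else:
                m = d - direction  # step back toward focal
                while row[m] == MISSING or not _matches(
                    row[m], founder.alleles[m]
                ):
                    if m == focal:
                        break
                    m -= direction
                if censoring == "midpoint":
                    bp = (float(pos[d]) + float(pos[m])) / 2.0
                elif censoring == "last-match":
                    bp = float(pos[m])
                else:
                    bp = float(pos[d])
                store[k] = marker_map.morgans_from_focal(bp)

    lg = [fam_group[f][0] for f in families]
    rg = [fam_group[f][1] for f in families]
    return SegmentData(
        chromosome_labels=list(matrix.chromosome_labels),
        left=left,
        right=right,
        left_censored=lcen,
        right_censored=rcen,
        families=families,
        left_group=lg,
        right_group=rg,
    )
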