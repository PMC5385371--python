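"""Partition chromosomes into dense and sparse variation blocks (dVBs / sVBs).

Dense variation blocks are chromosomal segments carrying many variants
relative to the reference genome.  Because recombination inside them is
suppressed they are inherited largely intact, which makes them the unit of
identity comparison between cultivars: two overlapping dVBs from different
cultivars that share nearly all their variants are taken to descend from a
common parental genome and get the same *type label*.

Segmentation uses a sliding-window scan: a window is dense when its variant
density reaches ``density_threshold`` (inclusive); the dense region is the
union of dense windows, gap-merged and minimum-width filtered.  All
thresholds in this module compare inclusively.
"""

from __future__ import annotations

import itertools
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

DENSE = "dense"
SPARSE = "sparse"


@dataclass(frozen=True)
class SegmentationParams:
    """Sliding-window segmentation parameters.

    Defaults (10 kb windows stepped by 2 kb, 1.5 variants/kb, 10 kb merge gap
    and minimum block width) produce dense blocks on the sub-100 kb scale
    typical of gene-rich regions at realistic resequencing densities.
    """

    window_bp: int = 10_000
    step_bp: int = 2_000
    density_threshold: float = 1.5  # variants per kb, inclusive
    min_block_bp: int = 10_000
    merge_gap_bp: int = 10_000

    def __post_init__(self) -> None:
        if not (self.window_bp >= self.step_bp >= 1):
            raise ValueError("require window_bp >= step_bp >= 1")
        if self.density_threshold <= 0:
            raise ValueError("density_threshold must be > 0")
        if self.min_block_bp < 1:
            raise ValueError("min_block_bp must be >= 1")


@dataclass(frozen=True)
class TypingParams:
    """Thresholds deciding whether two dVBs are of an identical type.

    Two overlapping dense blocks are the same type when their sequence
    identity is at least ``min_identity`` (99.8% by default) and their SNV
    concordance at least ``min_concordance`` (0.8).  Identity may be omitted
    (``use_identity=False``) when consensus sequences are unavailable.
    """

    min_identity: float = 0.998
    min_concordance: float = 0.8
    min_reciprocal_overlap: float = 0.5
    use_identity: bool = True

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_concordance", "min_reciprocal_overlap"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class VariationBlock:
    """A chromosomal interval classified dense or sparse for one cultivar.

    Coordinates are 1-based inclusive.  ``type_label`` is only ever set on
    dense blocks, after cross-cultivar typing.
    """

    chrom: str
    start: int
    end: int
    klass: str  # DENSE or SPARSE
    cultivar: str | None = None
    density: float = 0.0  # variants per kb
    type_label: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.klass == SPARSE and self.type_label is not None:
            raise ValueError("sparse blocks cannot carry a type label")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "VariationBlock") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def _density(count: int, length_bp: int) -> float:
    return count / (length_bp / 1000.0)


def segment_variation_blocks(
    variant_positions: Sequence[int],
    chrom_len: int,
    params: SegmentationParams | None = None,
    chrom: str = "chr",
    cultivar: str | None = None,
) -> list[VariationBlock]:
    """Segment one cultivar's chromosome into alternating dense/sparse blocks.

    ``variant_positions`` must be sorted 1-based positions within
    ``[1, chrom_len]``.  The returned blocks tile ``[1, chrom_len]`` without
    overlap; every dense block has density >= the threshold at window scale.
    """
    params = params or SegmentationParams()
    positions = list(variant_positions)
    if any(b < a for a, b in zip(positions, positions[1:])):
        positions = sorted(positions)
    if positions and (positions[0] < 1 or positions[-1] > chrom_len):
        raise ValueError("variant position outside [1, chrom_len]")

    # classify sliding windows, collect dense window intervals
    dense_ivals: list[tuple[int, int]] = []
    for wstart in range(1, chrom_len + 1, params.step_bp):
        wend = min(wstart + params.window_bp - 1, chrom_len)
        count = bisect_right(positions, wend) - bisect_left(positions, wstart)
        if _density(count, wend - wstart + 1) >= params.density_threshold:
            dense_ivals.append((wstart, wend))
        if wend == chrom_len:
            break

    # union of dense windows, then merge across small gaps
    merged: list[list[int]] = []
    for s, e in dense_ivals:
        if merged and s <= merged[-1][1] + 1 + params.merge_gap_bp:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    # minimum-width filter: short dense blocks are reclassified sparse
    dense_final = [
        (s, e) for s, e in merged if (e - s + 1) >= params.min_block_bp
    ]

    blocks: list[VariationBlock] = []
    cursor = 1

    def _emit(s: int, e: int, klass: str) -> None:
        count = bisect_right(positions, e) - bisect_left(positions, s)
        blocks.append(
            VariationBlock(
                chrom=chrom,
                start=s,
                end=e,
                klass=klass,
                cultivar=cultivar,
                density=_density(count, e - s + 1),
            )
        )

    for s, e in dense_final:
        if s > cursor:
            _emit(cursor, s - 1, SPARSE)
        _emit(s, e, DENSE)
        cursor = e + 1
    if cursor <= chrom_len:
        _emit(cursor, chrom_len, SPARSE)
    return blocks


def snv_concordance(
    block_a_variants: Iterable[tuple[int, str]],
    block_b_variants: Iterable[tuple[int, str]],
) -> float:
    """Jaccard concordance of two blocks' (position, alt-allele) sets.

    Returns ``|A n B| / |A u B|``; 1.0 when both sets are empty (two blocks
    both identical to the reference agree trivially).
    """
    a, b = set(block_a_variants), set(block_b_variants)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def approximate_identity(
    block_a_variants: Iterable[tuple[int, str]],
    block_b_variants: Iterable[tuple[int, str]],
    intersection_len: int,
) -> float:
    """Sequence identity proxy from variant calls alone.

    True identity needs consensus sequences; from VCF we approximate it as
    ``1 - discordant variant positions / intersection length``, where a
    discordant position is called non-reference in exactly one block or with
    different alt alleles.
    """
    if intersection_len <= 0:
        return 0.0
    a, b = set(block_a_variants), set(block_b_variants)
    discordant_positions = {pos for pos, _ in a ^ b}
    return 1.0 - len(discordant_positions) / intersection_len


@dataclass
class TypingResult:
    """Typed dense blocks plus diagnostics from cross-cultivar typing."""

    blocks: list[VariationBlock]
    n_loci: int
    n_types: int
    warnings: list[str] = field(default_factory=list)

    @property
    def per_locus_count(self) -> int:
        """Count of dVBs as reference-anchored loci."""
        return self.n_loci

    @property
    def per_cultivar_count(self) -> int:
        """Count of dVBs summed over cultivars."""
        return len(self.blocks)


def assign_block_types(
    dense_blocks: Sequence[VariationBlock],
    block_variants: Sequence[Iterable[tuple[int, str]]],
    params: TypingParams | None = None,
    pairwise_identity: Mapping[tuple[int, int], float] | None = None,
) -> TypingResult:
    """Assign shared type labels to dense blocks from all cultivars.

    Blocks overlapping reciprocally by at least ``min_reciprocal_overlap``
    form candidate pairs; a pair is linked when its SNV concordance (and,
    when available, sequence identity) passes the thresholds.  Types are the
    connected components of the link graph — transitive closure, mirroring
    same-colour typing across cultivars — so non-transitive triangles are
    possible and reported as warnings.  Labels are dense consecutive
    integers ordered along the genome.

    ``block_variants[i]`` is block i's (position, alt-allele) set;
    ``pairwise_identity`` optionally supplies exact identities keyed by block
    index pair, overriding the VCF-based approximation.
    """
    params = params or TypingParams()
    if len(dense_blocks) != len(block_variants):
        raise ValueError("need one variant set per block")
    variant_sets = [set(v) for v in block_variants]
    n = len(dense_blocks)

    overlap_graph = nx.Graph()
    overlap_graph.add_nodes_from(range(n))
    link_graph = nx.Graph()
    link_graph.add_nodes_from(range(n))

    by_chrom: dict[str, list[int]] = {}
    for i, b in enumerate(dense_blocks):
        if b.klass != DENSE:
            raise ValueError("assign_block_types expects dense blocks only")
        by_chrom.setdefault(b.chrom, []).append(i)

    identity_approximated = False
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: dense_blocks[i].start)
        for ai in range(len(idxs)):
            i = idxs[ai]
            bi = dense_blocks[i]
            for aj in range(ai + 1, len(idxs)):
                j = idxs[aj]
                bj = dense_blocks[j]
                if bj.start > bi.end:
                    break
                ov = bi.overlap(bj)
                if ov / bi.length < params.min_reciprocal_overlap:
                    continue
                if ov / bj.length < params.min_reciprocal_overlap:
                    continue
                overlap_graph.add_edge(i, j)
                lo = max(bi.start, bj.start)
                hi = min(bi.end, bj.end)
                in_ival_a = {v for v in variant_sets[i] if lo <= v[0] <= hi}
                in_ival_b = {v for v in variant_sets[j] if lo <= v[0] <= hi}
                conc = snv_concordance(in_ival_a, in_ival_b)
                if conc < params.min_concordance:
                    continue
                if params.use_identity:
                    if pairwise_identity is not None:
                        ident = pairwise_identity.get(
                            (i, j), pairwise_identity.get((j, i), 1.0)
                        )
                    else:
                        ident = approximate_identity(
                            in_ival_a, in_ival_b, hi - lo + 1
                        )
                        identity_approximated = True
                    if ident < params.min_identity:
                        continue
                link_graph.add_edge(i, j, concordance=conc)

    warning_msgs: list[str] = []
    if identity_approximated:
        msg = (
            "sequence identity approximated from variant calls "
            "(no consensus sequences supplied)"
        )
        warning_msgs.append(msg)
        warnings.warn(msg, stacklevel=2)

    components = [sorted(c) for c in nx.connected_components(link_graph)]
    components.sort(
        key=lambda c: (dense_blocks[c[0]].chrom, dense_blocks[c[0]].start)
    )
    labeled = list(dense_blocks)
    for label, comp in enumerate(components):
        for i in comp:
            labeled[i] = replace(dense_blocks[i], type_label=label)
        # non-transitive triangles within a component: linked via closure
        for i, j in itertools.combinations(comp, 2):
            if link_graph.has_edge(i, j):
                continue
            if not overlap_graph.has_edge(i, j):
                continue
            msg = (
                f"non-metric cluster: blocks {i} and {j} share type {label} "
                "by transitive closure but fail pairwise thresholds"
            )
            warning_msgs.append(msg)
            warnings.warn(msg, stacklevel=2)

    n_loci = nx.number_connected_components(overlap_graph)
    return TypingResult(
        blocks=labeled,
        n_loci=n_loci,
        n_types=len(components),
        warnings=warning_msgs,
    )
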