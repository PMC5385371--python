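"""Synthetic founder/cross panels with variation-block structure.

Generates what the pipeline assumes about real resequencing panels, at desk
scale: chromosomes tiled by planted dense variation blocks (dVBs, many
variants, inherited largely intact) and sparse blocks (sVBs, near-identical
to the reference), founders sharing ancestral dVB haplotypes, and crossed /
selfed / backcrossed descendants whose genomes are founder mosaics.
Crossovers fall with per-bp intensity 1 inside dVBs and ``recomb_ratio``
(default 6.6) inside sVBs, the suppression that makes dVBs a stable unit of
identity.  No crossover interference is modelled, and no nucleotide
sequences are generated — variants are (position, allele-length) records,
which is all the marker pipeline consumes.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from vbcode.io_formats import MISSING, GenotypeTable, VariantRecord
from vbcode.vb_segmentation import DENSE, SPARSE, VariationBlock


class Variant(NamedTuple):
    """A simulated variant: 1-based position, allele lengths, allele tag."""

    pos: int
    ref_len: int
    alt_len: int
    tag: str  # distinguishes alt alleles at the same position


Segment = tuple[int, int, int]  # (start, end, founder index), 1-based inclusive


@dataclass(frozen=True)
class CrossSimConfig:
    """Study conditions for the synthetic panel.

    Densities are variants per kb; dense regions are an order of magnitude
    denser than sparse ones, as in resequenced cultivar genomes.  InDel
    sizes span 1–30 bp so the 5–20 bp marker filter sees both passes and
    failures.  ``recomb_ratio`` is the sVB:dVB per-bp crossover rate ratio;
    ``founder_share_prob`` is the chance a founder reuses an earlier
    founder's ancestral haplotype in a dVB, which creates shared block
    types.  The seed fixes every downstream draw.
    """

    n_founders: int = 6
    n_chromosomes: int = 2
    chrom_len: int = 1_000_000
    n_dvb_per_chrom: int = 8
    dvb_len_mean: int = 40_000
    dvb_len_sd: int = 8_000
    min_svb_gap: int = 40_000
    dense_density: float = 3.0
    sparse_density: float = 0.05
    indel_fraction: float = 0.35
    indel_size_range: tuple[int, int] = (1, 30)
    founder_share_prob: float = 0.3
    recomb_ratio: float = 6.6
    crossovers_per_chrom: float = 2.0
    selfing_generations: int = 4
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recomb_ratio <= 1:
            raise ValueError("recomb_ratio must be > 1 (sVBs recombine more)")
        if not (self.dense_density > self.sparse_density >= 0):
            raise ValueError("require dense_density > sparse_density >= 0")


@dataclass
class MosaicGenome:
    """A diploid genome as two founder-mosaic haplotypes per chromosome."""

    name: str
    haplotypes: dict[str, tuple[list[Segment], list[Segment]]]

    def founder_at(self, chrom: str, pos: int, hap: int) -> int:
        for s, e, f in self.haplotypes[chrom][hap]:
            if s <= pos <= e:
                return f
        raise ValueError(f"position {chrom}:{pos} outside chromosome")

    def validate_tiling(self, chrom_len: int) -> None:
        for hap_pair in self.haplotypes.values():
            for hap in hap_pair:
                cursor = 1
                for s, e, _ in hap:
                    if s != cursor or e < s:
                        raise ValueError("haplotype segments do not tile")
                    cursor = e + 1
                if cursor != chrom_len + 1:
                    raise ValueError("haplotype segments do not tile")


def _splice(hap: list[Segment], lo: int, hi: int) -> list[Segment]:
    """Sub-segments of ``hap`` clipped to [lo, hi]."""
    out: list[Segment] = []
    for s, e, f in hap:
        if e < lo:
            continue
        if s > hi:
            break
        out.append((max(s, lo), min(e, hi), f))
    return out


def genome_haps(genome: MosaicGenome, chrom: str) -> tuple[list[Segment], list[Segment]]:
    return genome.haplotypes[chrom]


def _merge(segments: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segments:
        if out and out[-1][2] == seg[2] and out[-1][1] + 1 == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


class SyntheticPanel:
    """Founders plus machinery to breed and genotype descendants.

    Construct with :meth:`simulate_founders`; everything downstream
    (gametes, crosses, genotype tables, variant records) hangs off the
    instance.  All randomness flows through the generator created from
    ``config.seed`` unless an explicit ``rng`` is passed.
    """

    def __init__(
        self,
        config: CrossSimConfig,
        layout: dict[str, list[VariationBlock]],
        founder_variants: list[dict[str, dict[int, Variant]]],
        block_types: dict[str, list[list[int]]],
    ) -> None:
        self.config = config
        self.layout = layout
        self.founder_variants = founder_variants
        self.block_types = block_types  # chrom -> per dense block -> per founder type id
        self.rng = np.random.default_rng(config.seed + 1)
        self._intensity_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        # sorted position index per founder per chromosome, for fast slicing
        self._pos_index: dict[tuple[int, str], list[int]] = {
            (f, chrom): sorted(fv[chrom])
            for f, fv in enumerate(founder_variants)
            for chrom in fv
        }

    def _positions_in(self, founder: int, chrom: str, start: int, end: int):
        index = self._pos_index[(founder, chrom)]
        lo = bisect_left(index, start)
        hi = bisect_right(index, end)
        return index[lo:hi]

    # ------------------------------------------------------------------ setup

    @classmethod
    def simulate_founders(cls, config: CrossSimConfig) -> "SyntheticPanel":
        """Plant the dVB/sVB layout and draw per-founder variant sets.

        Founders share ancestral dVB haplotypes with probability
        ``founder_share_prob`` (assigned by copying a uniformly chosen
        earlier founder's type), so cross-cultivar typing has non-trivial
        structure: same-type blocks carry identical variant sets.  Sparse
        regions carry founder-private variants only.
        """
        rng = np.random.default_rng(config.seed)
        layout: dict[str, list[VariationBlock]] = {}
        founder_variants: list[dict[str, dict[int, Variant]]] = [
            {} for _ in range(config.n_founders)
        ]
        block_types: dict[str, list[list[int]]] = {}

        for c in range(config.n_chromosomes):
            chrom = f"chr{c + 1:02d}"
            blocks = cls._plant_layout(chrom, config, rng)
            layout[chrom] = blocks
            for fv in founder_variants:
                fv[chrom] = {}
            dense = [b for b in blocks if b.klass == DENSE]
            chrom_types: list[list[int]] = []
            for block in dense:
                type_variants: list[dict[int, Variant]] = []
                assignment: list[int] = []
                for f in range(config.n_founders):
                    if (
                        f > 0
                        and rng.random() < config.founder_share_prob
                        and type_variants
                    ):
                        t = assignment[int(rng.integers(f))]
                    else:
                        t = len(type_variants)
                        type_variants.append(
                            cls._draw_block_variants(
                                block, config.dense_density, config, rng
                            )
                        )
                    assignment.append(t)
                    founder_variants[f][chrom].update(type_variants[t])
                chrom_types.append(assignment)
            block_types[chrom] = chrom_types
            # founder-private variants in sparse regions
            if config.sparse_density > 0:
                for f in range(config.n_founders):
                    for block in blocks:
                        if block.klass != SPARSE:
                            continue
                        founder_variants[f][chrom].update(
                            cls._draw_block_variants(
                                block, config.sparse_density, config, rng
                            )
                        )
        return cls(config, layout, founder_variants, block_types)

    @staticmethod
    def _plant_layout(
        chrom: str, config: CrossSimConfig, rng: np.random.Generator
    ) -> list[VariationBlock]:
        n = config.n_dvb_per_chrom
        lens = np.clip(
            rng.normal(config.dvb_len_mean, config.dvb_len_sd, size=n),
            15_000,
            90_000,
        ).astype(int)
        slack = config.chrom_len - int(lens.sum()) - (n + 1) * config.min_svb_gap
        if slack < 0:
            raise ValueError(
                "chromosome too short for the requested dVB layout"
            )
        extra = rng.multinomial(slack // 100, np.full(n + 1, 1.0 / (n + 1))) * 100
        gaps = config.min_svb_gap + extra
        blocks: list[VariationBlock] = []
        cursor = 1
        for i in range(n):
            gap_end = cursor + int(gaps[i]) - 1
            blocks.append(
                VariationBlock(chrom=chrom, start=cursor, end=gap_end, klass=SPARSE)
            )
            dvb_end = gap_end + int(lens[i])
            blocks.append(
                VariationBlock(
                    chrom=chrom, start=gap_end + 1, end=dvb_end, klass=DENSE
                )
            )
            cursor = dvb_end + 1
        blocks.append(
            VariationBlock(
                chrom=chrom, start=cursor, end=config.chrom_len, klass=SPARSE
            )
        )
        return blocks

    @staticmethod
    def _draw_block_variants(
        block: VariationBlock,
        density_per_kb: float,
        config: CrossSimConfig,
        rng: np.random.Generator,
    ) -> dict[int, Variant]:
        n = rng.poisson(density_per_kb * block.length / 1000.0)
        positions = np.unique(
            rng.integers(block.start, block.end + 1, size=n)
        )
        out: dict[int, Variant] = {}
        lo, hi = config.indel_size_range
        for pos in positions:
            serial = int(rng.integers(1_000_000))
            if rng.random() < config.indel_fraction:
                size = int(rng.integers(lo, hi + 1))
                if rng.random() < 0.5:  # deletion
                    ref_len, alt_len = 1 + size, 1
                else:  # insertion
                    ref_len, alt_len = 1, 1 + size
            else:  # SNV
                ref_len = alt_len = 1
            out[int(pos)] = Variant(
                pos=int(pos),
                ref_len=ref_len,
                alt_len=alt_len,
                tag=f"v{serial}",
            )
        return out

    # ------------------------------------------------------------- truth sets

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.config.chrom_len for c in self.layout}

    def planted_dense_blocks(self, chrom: str) -> list[VariationBlock]:
        return [b for b in self.layout[chrom] if b.klass == DENSE]

    def founder_names(self) -> list[str]:
        return [f"F{i:02d}" for i in range(self.config.n_founders)]

    def founder_genome(self, index: int) -> MosaicGenome:
        L = self.config.chrom_len
        return MosaicGenome(
            name=f"F{index:02d}",
            haplotypes={
                chrom: ([(1, L, index)], [(1, L, index)])
                for chrom in self.layout
            },
        )

    # --------------------------------------------------------------- meiosis

    def _intensity(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant crossover intensity over the planted layout."""
        if chrom not in self._intensity_cache:
            starts, cum = [], [0.0]
            for b in self.layout[chrom]:
                rate = 1.0 if b.klass == DENSE else self.config.recomb_ratio
                starts.append(b.start)
                cum.append(cum[-1] + rate * b.length)
            self._intensity_cache[chrom] = (
                np.asarray(starts, dtype=float),
                np.asarray(cum, dtype=float),
            )
        return self._intensity_cache[chrom]

    def sample_crossovers(
        self, chrom: str, rng: np.random.Generator | None = None
    ) -> list[int]:
        """Crossover breakpoints for one meiosis on one chromosome.

        Count is Poisson(``crossovers_per_chrom``); positions are drawn by
        inverse CDF over the piecewise intensity (dVB weight 1, sVB weight
        ``recomb_ratio`` per bp).  A breakpoint at x means the gamete
        switches source haplotype after position x.
        """
        rng = rng if rng is not None else self.rng
        starts, cum = self._intensity(chrom)
        blocks = self.layout[chrom]
        n = rng.poisson(self.config.crossovers_per_chrom)
        points: list[int] = []
        total = cum[-1]
        for u in rng.random(n) * total:
            i = int(np.searchsorted(cum, u, side="right")) - 1
            i = min(i, len(blocks) - 1)
            b = blocks[i]
            rate = 1.0 if b.klass == DENSE else self.config.recomb_ratio
            offset = (u - cum[i]) / rate
            points.append(min(b.start + int(offset), b.end))
        return sorted(set(points))

    def gamete(
        self, genome: MosaicGenome, rng: np.random.Generator | None = None
    ) -> dict[str, list[Segment]]:
        rng = rng if rng is not None else self.rng
        L = self.config.chrom_len
        out: dict[str, list[Segment]] = {}
        for chrom in self.layout:
            breaks = self.sample_crossovers(chrom, rng)
            phase = int(rng.integers(2))
            segments: list[Segment] = []
            lo = 1
            for x in breaks + [L]:
                hi = min(x, L)
                if hi >= lo:
                    segments.extend(
                        _splice(genome.haplotypes[chrom][phase], lo, hi)
                    )
                lo = hi + 1
                phase = 1 - phase
            out[chrom] = _merge(segments)
        return out

    # ---------------------------------------------------------------- crosses

    def cross(
        self,
        parent_a: MosaicGenome,
        parent_b: MosaicGenome,
        name: str,
        rng: np.random.Generator | None = None,
    ) -> MosaicGenome:
        rng = rng if rng is not None else self.rng
        ga, gb = self.gamete(parent_a, rng), self.gamete(parent_b, rng)
        return MosaicGenome(
            name=name,
            haplotypes={c: (ga[c], gb[c]) for c in self.layout},
        )

    def self_cross(
        self, genome: MosaicGenome, name: str | None = None,
        rng: np.random.Generator | None = None,
    ) -> MosaicGenome:
        return self.cross(genome, genome, name or genome.name, rng)

    def inbred_line(
        self,
        parent_a: MosaicGenome,
        parent_b: MosaicGenome,
        name: str,
        generations: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> MosaicGenome:
        """F1 followed by ``generations`` rounds of selfing (Fn line)."""
        rng = rng if rng is not None else self.rng
        g = self.cross(parent_a, parent_b, name, rng)
        n = (
            generations
            if generations is not None
            else self.config.selfing_generations
        )
        for _ in range(n):
            g = self.self_cross(g, name, rng)
        return g

    def backcross(
        self,
        donor: MosaicGenome,
        recurrent: MosaicGenome,
        name: str,
        n_generations: int,
        selfing_generations: int = 0,
        rng: np.random.Generator | None = None,
    ) -> MosaicGenome:
        """BC_n line: F1(donor x recurrent), then n backcrosses to recurrent.

        The BC_n genome retains an expected (1/2)^(n+1) of the donor genome.
        Optional terminal selfing fixes residual heterozygous segments, as
        in backcross-inbred cultivar development.
        """
        rng = rng if rng is not None else self.rng
        g = self.cross(donor, recurrent, name, rng)
        for _ in range(n_generations):
            g = self.cross(g, recurrent, name, rng)
        for _ in range(selfing_generations):
            g = self.self_cross(g, name, rng)
        return g

    def breed_panel(
        self,
        n_cultivars: int,
        rng: np.random.Generator | None = None,
        prefix: str = "C",
    ) -> list[MosaicGenome]:
        """Inbred cultivars from random founder pairs (F1 then selfing)."""
        rng = rng if rng is not None else self.rng
        founders = [
            self.founder_genome(i) for i in range(self.config.n_founders)
        ]
        out: list[MosaicGenome] = []
        for k in range(n_cultivars):
            i, j = rng.choice(self.config.n_founders, size=2, replace=False)
            out.append(
                self.inbred_line(
                    founders[i], founders[j], f"{prefix}{k:03d}", rng=rng
                )
            )
        return out

    # ------------------------------------------------------------ genotyping

    def donor_fraction(self, genome: MosaicGenome, donor_index: int) -> float:
        """Diploid bp fraction of the genome originating from one founder."""
        total = donor = 0
        for hap_pair in genome.haplotypes.values():
            for hap in hap_pair:
                for s, e, f in hap:
                    total += e - s + 1
                    if f == donor_index:
                        donor += e - s + 1
        return donor / total

    def _hap_allele(self, chrom: str, pos: int, founder: int) -> Variant | None:
        return self.founder_variants[founder][chrom].get(pos)

    def variant_positions(self, genome: MosaicGenome, chrom: str) -> list[int]:
        """Sorted positions where the cultivar carries any non-reference allele."""
        positions: set[int] = set()
        for hap in genome.haplotypes[chrom]:
            for s, e, f in hap:
                positions.update(self._positions_in(f, chrom, s, e))
        return sorted(positions)

    def variant_set(
        self, genome: MosaicGenome, chrom: str, start: int, end: int
    ) -> set[tuple[int, str]]:
        """(position, allele-tag) pairs carried in an interval, for typing."""
        out: set[tuple[int, str]] = set()
        for hap in genome.haplotypes[chrom]:
            for s, e, f in _splice(hap, start, end):
                fv = self.founder_variants[f][chrom]
                for pos in self._positions_in(f, chrom, s, e):
                    out.add((pos, fv[pos].tag))
        return out

    def marker_call(
        self,
        genome: MosaicGenome,
        chrom: str,
        pos: int,
        ref_len: int,
        rng: np.random.Generator | None = None,
    ) -> str:
        """Band pattern at a locus: allele length per haplotype, ``x/y`` if het."""
        labels = []
        for hap in range(2):
            f = genome.founder_at(chrom, pos, hap)
            var = self._hap_allele(chrom, pos, f)
            labels.append(str(var.alt_len if var is not None else ref_len))
        if self.config.mutation_rate > 0:
            rng = rng if rng is not None else self.rng
            for i in range(2):
                if rng.random() < self.config.mutation_rate:
                    labels[i] = str(int(labels[i]) + int(rng.integers(1, 4)))
        a, b = sorted(labels)
        return a if a == b else f"{a}/{b}"

    def genotype_panel(
        self,
        genomes: Sequence[MosaicGenome],
        loci: Sequence[tuple[str, int]],
        rng: np.random.Generator | None = None,
    ) -> GenotypeTable:
        """Genotype cultivars at marker loci as band-size patterns.

        The reference pattern at each locus is the reference allele length;
        it is recorded in ``ref_patterns`` so encoding works even when no
        reference-identical cultivar is present.  Per-marker mutation noise
        is applied at the configured rate.
        """
        ref_lens = {
            (chrom, pos): self._ref_len_at(chrom, pos) for chrom, pos in loci
        }
        marker_ids = [f"{chrom}_{pos}" for chrom, pos in loci]
        rows = {}
        for g in genomes:
            for chrom, pos in loci:
                if not (1 <= pos <= self.config.chrom_len):
                    raise ValueError(f"locus {chrom}:{pos} outside chromosome")
            rows[g.name] = [
                self.marker_call(g, chrom, pos, ref_lens[(chrom, pos)], rng)
                for chrom, pos in loci
            ]
        data = pd.DataFrame.from_dict(rows, orient="index", columns=marker_ids)
        ref_patterns = {
            f"{chrom}_{pos}": str(ref_lens[(chrom, pos)])
            for chrom, pos in loci
        }
        marker_dvb = {}
        for (chrom, pos), mid in zip(loci, marker_ids):
            for k, b in enumerate(self.planted_dense_blocks(chrom)):
                if b.start <= pos <= b.end:
                    marker_dvb[mid] = f"{chrom}:dVB{k}"
                    break
        return GenotypeTable(data, marker_dvb=marker_dvb, ref_patterns=ref_patterns)

    def _ref_len_at(self, chrom: str, pos: int) -> int:
        lens = [
            fv[chrom][pos].ref_len
            for fv in self.founder_variants
            if pos in fv[chrom]
        ]
        return max(lens) if lens else 1

    def emit_variant_records(
        self, genomes: Sequence[MosaicGenome]
    ) -> list[VariantRecord]:
        """Multi-sample variant records over all sites segregating in ``genomes``.

        Allele strings are placeholder runs of distinct letters with the
        simulated lengths (no nucleotide sequence is modelled); genotypes
        are per-haplotype allele indices.
        """
        records: list[VariantRecord] = []
        letters = "ACGTMRWSYKVHDBN"
        for chrom in self.layout:
            # per-genome, per-haplotype carried variants via segment slicing
            hap_maps: list[tuple[str, dict[int, Variant], dict[int, Variant]]] = []
            sites: dict[int, dict[str, Variant]] = {}
            for g in genomes:
                maps = []
                for hap in genome_haps(g, chrom):
                    m: dict[int, Variant] = {}
                    for s, e, f in hap:
                        fv = self.founder_variants[f][chrom]
                        for pos in self._positions_in(f, chrom, s, e):
                            m[pos] = fv[pos]
                    maps.append(m)
                hap_maps.append((g.name, maps[0], maps[1]))
                for m in maps:
                    for pos, v in m.items():
                        sites.setdefault(pos, {})[v.tag] = v
            for pos in sorted(sites):
                variants_here = [
                    sites[pos][tag] for tag in sorted(sites[pos])
                ]
                tags = {v.tag: k for k, v in enumerate(variants_here)}
                ref = "A" * max(v.ref_len for v in variants_here)
                alts = tuple(
                    letters[(k + 1) % len(letters)] * v.alt_len
                    for k, v in enumerate(variants_here)
                )
                genotypes = {}
                for name, m0, m1 in hap_maps:
                    pair = tuple(
                        0 if (v := m.get(pos)) is None else tags[v.tag] + 1
                        for m in (m0, m1)
                    )
                    genotypes[name] = pair
                records.append(
                    VariantRecord(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alts=alts,
                        genotypes=genotypes,
                    )
                )
        return records

    # ----------------------------------------------------------- estimation

    def estimate_recomb_ratio(
        self, n_meioses: int, rng: np.random.Generator | None = None
    ) -> float:
        """Per-bp sVB:dVB crossover-rate ratio from simulated meioses.

        Tallies realized crossover breakpoints against the planted layout
        and divides the per-bp rates.  With 10^4 meioses the estimate sits
        within a few percent of the configured ratio.
        """
        rng = rng if rng is not None else self.rng
        dense_bp = sparse_bp = 0
        for blocks in self.layout.values():
            for b in blocks:
                if b.klass == DENSE:
                    dense_bp += b.length
                else:
                    sparse_bp += b.length
        dense_co = sparse_co = 0
        chroms = list(self.layout)
        for _ in range(n_meioses):
            for chrom in chroms:
                for x in self.sample_crossovers(chrom, rng):
                    if any(
                        b.start <= x <= b.end
                        for b in self.planted_dense_blocks(chrom)
                    ):
                        dense_co += 1
                    else:
                        sparse_co += 1
        if dense_co == 0:
            raise ValueError("no dVB crossovers observed; increase n_meioses")
        return (sparse_co / sparse_bp) / (dense_co / dense_bp)
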