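"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the VCF convention);
BED export is the single point of translation to 0-based half-open.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from skbio import TreeNode

MISSING = "."


class UnknownSampleError(KeyError):
    """A requested sample is absent from the VCF header."""


class UnsortedVCFError(ValueError):
    """Records are not in (chrom, pos) order."""


class OverlappingBlocksError(ValueError):
    """Blocks handed to the BED writer overlap on a chromosome."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant call site, possibly multi-allelic, with per-sample genotypes.

    ``pos`` is the 1-based reference position.  ``genotypes`` maps sample name
    to an ordered pair of allele indices (0 = ref) with ``None`` for missing
    calls.  Multi-allelic records are kept intact so third-allele patterns
    survive downstream.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: Mapping[str, tuple[int | None, int | None]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        n_alt = len(self.alts)
        for sample, gt in self.genotypes.items():
            for idx in gt:
                if idx is not None and not (0 <= idx <= n_alt):
                    raise ValueError(
                        f"allele index {idx} out of range for sample {sample}"
                    )

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def allele_length(self, index: int) -> int:
        return len(self.alleles[index])

    @property
    def is_indel(self) -> bool:
        """True when any allele length differs from the reference length."""
        return any(len(a) != len(self.ref) for a in self.alts)

    @property
    def indel_size(self) -> int:
        """Largest absolute length difference between an alt and the ref."""
        if not self.alts:
            return 0
        return max(abs(len(a) - len(self.ref)) for a in self.alts)

    def carries_alt(self, sample: str) -> bool:
        gt = self.genotypes.get(sample)
        if gt is None:
            return False
        return any(i is not None and i > 0 for i in gt)


def read_vcf(
    path: str | os.PathLike,
    sample_subset: Sequence[str] | None = None,
) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` from a VCF 4.x file in (chrom, pos) order.

    Multi-allelic records are yielded as single records, not split.  Raises
    :class:`UnknownSampleError` if a requested sample is missing and
    :class:`UnsortedVCFError` if positions go backwards within a chromosome.
    """
    with pysam.VariantFile(os.fspath(path)) as vf:
        header_samples = list(vf.header.samples)
        if sample_subset is not None:
            missing = [s for s in sample_subset if s not in header_samples]
            if missing:
                raise UnknownSampleError(
                    f"unknown sample(s): {', '.join(missing)}"
                )
            samples = list(sample_subset)
        else:
            samples = header_samples

        last: tuple[str, int] | None = None
        for rec in vf:
            pos = rec.pos  # pysam exposes the 1-based POS here
            if last is not None and rec.chrom == last[0] and pos < last[1]:
                raise UnsortedVCFError(
                    f"unsorted input at {rec.chrom}:{pos} after {last[1]}"
                )
            last = (rec.chrom, pos)
            genotypes: dict[str, tuple[int | None, int | None]] = {}
            for s in samples:
                allele_ids = rec.samples[s].allele_indices
                if allele_ids is None:
                    genotypes[s] = (None, None)
                else:
                    pair = tuple(allele_ids)
                    if len(pair) == 1:
                        pair = (pair[0], pair[0])
                    genotypes[s] = pair  # type: ignore[assignment]
            yield VariantRecord(
                chrom=rec.chrom,
                pos=pos,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                genotypes=genotypes,
            )


def read_chrom_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column TSV of chromosome name and length in bp."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            lengths[chrom] = int(length)
    return lengths


def write_chrom_lengths(lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def write_blocks_bed(blocks: Iterable, path: str | os.PathLike) -> None:
    """Write variation blocks as BED (0-based, half-open).

    The name column carries the block class plus type label, the score column
    the variant density in variants/kb.  Blocks must not overlap within a
    chromosome.
    """
    blocks = sorted(blocks, key=lambda b: (b.chrom, b.start, b.end))
    prev_by_chrom: dict[str, int] = {}
    for b in blocks:
        if b.start > b.end:
            raise ValueError(f"block start {b.start} > end {b.end}")
        prev_end = prev_by_chrom.get(b.chrom, 0)
        if b.start <= prev_end:  # 1-based: overlap iff start <= previous end
            raise OverlappingBlocksError(
                f"overlapping blocks on {b.chrom} at {b.start}"
            )
        prev_by_chrom[b.chrom] = b.end
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\n")
        for b in blocks:
            label = b.klass
            if getattr(b, "type_label", None) is not None:
                label = f"{b.klass}:{b.type_label}"
            fh.write(
                f"{b.chrom}\t{b.start - 1}\t{b.end}\t{label}\t{b.density:.4f}\n"
            )


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    """Write a tree as Newick; round-trips through :func:`parse_newick`."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree))
        fh.write("\n")


def newick_string(tree: TreeNode) -> str:
    if tree.is_tip():  # degenerate single-leaf tree
        return f"{tree.name}:{tree.length or 0.0};"
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def parse_newick(source: str | os.PathLike) -> TreeNode:
    """Parse a Newick file path or literal Newick string into a tree."""
    if isinstance(source, str) and source.rstrip().endswith(";"):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    stripped = text.strip()
    # skbio rejects the bare one-leaf form, handle it directly
    if stripped.endswith(";") and "(" not in stripped:
        body = stripped[:-1]
        name, _, length = body.partition(":")
        tip = TreeNode(name=name or None)
        tip.length = float(length) if length else None
        return tip
    return TreeNode.read(io.StringIO(text), format="newick")


def write_variant_tsv(
    records: Iterable[VariantRecord], path: str | os.PathLike
) -> None:
    """Write variant records as a plain TSV (chrom, pos, ref, alts, genotypes).

    A text stand-in for multi-sample VCF used by the simulator's emission;
    genotypes are ``i/j`` allele-index pairs with ``./.`` for missing.
    """
    records = list(records)
    samples: list[str] = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talts\t" + "\t".join(samples) + "\n")
        for rec in records:
            gts = []
            for s in samples:
                gt = rec.genotypes.get(s, (None, None))
                gts.append(
                    "/".join("." if i is None else str(i) for i in gt)
                )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t"
                + ",".join(rec.alts)
                + "\t"
                + "\t".join(gts)
                + "\n"
            )


def read_variant_tsv(path: str | os.PathLike) -> Iterator[VariantRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            chrom, pos, ref, alts = parts[0], int(parts[1]), parts[2], parts[3]
            genotypes = {}
            for s, g in zip(samples, parts[4:]):
                pair = tuple(
                    None if x == "." else int(x) for x in g.split("/")
                )
                if len(pair) == 1:
                    pair = (pair[0], pair[0])
                genotypes[s] = pair
            yield VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alts=tuple(a for a in alts.split(",") if a),
                genotypes=genotypes,
            )


def read_variants(path: str | os.PathLike) -> Iterator[VariantRecord]:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` via pysam, else TSV."""
    name = os.fspath(path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_variant_tsv(path)


def read_blocks_bed(path: str | os.PathLike) -> list:
    """Read blocks written by :func:`write_blocks_bed` back to 1-based form."""
    from vbcode.vb_segmentation import VariationBlock

    blocks = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start0, end, name, score = line.rstrip("\n").split("\t")[:5]
            klass, _, label = name.partition(":")
            blocks.append(
                VariationBlock(
                    chrom=chrom,
                    start=int(start0) + 1,
                    end=int(end),
                    klass=klass,
                    density=float(score),
                    type_label=int(label) if label else None,
                )
            )
    return blocks


class GenotypeTable:
    """Rectangular cultivar x marker table of allele-pattern labels.

    Patterns are band-size classes (strings); a heterozygous call is the two
    patterns joined by ``/`` in sorted order; missing cells are ``"."``.
    Serialized as TSV with a two-line header (marker id, then host dVB id).
    ``ref_patterns`` optionally declares the reference-genome pattern per
    marker, used when the reference cultivar itself has a missing call.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        marker_dvb: Mapping[str, str] | None = None,
        ref_patterns: Mapping[str, str] | None = None,
    ) -> None:
        if data.index.has_duplicates or data.columns.has_duplicates:
            raise ValueError("marker and cultivar ids must be unique")
        self.data = data.astype(str)
        self.marker_dvb = dict(marker_dvb or {})
        self.ref_patterns = dict(ref_patterns or {})

    @property
    def cultivars(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def cell(self, cultivar: str, marker: str) -> str:
        return self.data.at[cultivar, marker]

    def patterns(self, marker: str) -> list[str]:
        """Distinct single patterns observed at a marker (missing excluded)."""
        seen: list[str] = []
        for v in self.data[marker]:
            if v == MISSING:
                continue
            for p in v.split("/"):
                if p not in seen:
                    seen.append(p)
        return seen

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("marker\t" + "\t".join(self.markers) + "\n")
            fh.write(
                "dvb\t"
                + "\t".join(self.marker_dvb.get(m, ".") for m in self.markers)
                + "\n"
            )
            for cultivar in self.cultivars:
                row = "\t".join(self.data.loc[cultivar])
                fh.write(f"{cultivar}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GenotypeTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            dvb_line = fh.readline().rstrip("\n").split("\t")
            if header[0] != "marker" or dvb_line[0] != "dvb":
                raise ValueError("not a genotype table TSV (bad header)")
            markers = header[1:]
            marker_dvb = {
                m: d for m, d in zip(markers, dvb_line[1:]) if d != MISSING
            }
            rows: dict[str, list[str]] = {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or parts == [""]:
                    continue
                rows[parts[0]] = parts[1:]
        data = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
        return cls(data, marker_dvb=marker_dvb)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.data.equals(other.data) and self.marker_dvb == other.marker_dvb
        )
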