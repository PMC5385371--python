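"""End-to-end orchestration: variants in, barcode matrix out.

Chains segmentation, cross-cultivar typing, marker discovery and barcode
encoding over a multi-sample variant stream, which is what the CLI and the
full-pipeline tests drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from vbcode.barcode_codec import BarcodeMatrix, encode_genotypes
from vbcode.io_formats import MISSING, GenotypeTable, VariantRecord
from vbcode.marker_discovery import (
    DEFAULT_AMPLICON_WINDOW,
    DEFAULT_MAX_INDEL,
    DEFAULT_MIN_INDEL,
    InDelCandidate,
    MarkerPanel,
    default_flanks,
    extract_candidate_indels,
    select_markers,
)
from vbcode.vb_segmentation import (
    DENSE,
    SegmentationParams,
    TypingParams,
    TypingResult,
    VariationBlock,
    assign_block_types,
    segment_variation_blocks,
)


@dataclass
class PanelResult:
    """Everything the pipeline produced, one attribute per stage."""

    blocks_by_cultivar: dict[str, list[VariationBlock]]
    typing: TypingResult
    dvb_loci: list[VariationBlock]
    candidates: list[InDelCandidate]
    panel: MarkerPanel
    genotype_table: GenotypeTable
    barcodes: BarcodeMatrix


def merge_dense_loci(
    blocks_by_cultivar: Mapping[str, Sequence[VariationBlock]],
) -> list[VariationBlock]:
    """Reference-anchored dVB loci: the per-chromosome union of all
    cultivars' dense intervals, each merged interval one locus."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for blocks in blocks_by_cultivar.values():
        for b in blocks:
            if b.klass == DENSE:
                by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    loci: list[VariationBlock] = []
    label = 0
    for chrom in sorted(by_chrom):
        ivals = sorted(by_chrom[chrom])
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            loci.append(
                VariationBlock(
                    chrom=chrom, start=s, end=e, klass=DENSE, type_label=label
                )
            )
            label += 1
    return loci


def run_panel(
    records: Iterable[VariantRecord],
    chrom_lengths: Mapping[str, int],
    reference: str,
    seg_params: SegmentationParams | None = None,
    typing_params: TypingParams | None = None,
    min_indel: int = DEFAULT_MIN_INDEL,
    max_indel: int = DEFAULT_MAX_INDEL,
    amplicon_window: tuple[int, int] = DEFAULT_AMPLICON_WINDOW,
    per_dvb_quota: int = 1,
    max_missing_frac: float = 0.10,
) -> PanelResult:
    """Run segmentation -> typing -> marker discovery -> barcode encoding.

    ``records`` is a multi-sample variant stream against a shared reference;
    ``reference`` names the cultivar barcodes are keyed to.  If it is not
    among the samples a virtual all-reference row is added under that name
    (the reference genome trivially matches itself everywhere).
    """
    records = list(records)
    samples: list[str] = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)

    # per-cultivar non-reference positions, and carried (pos, alt) sets
    positions: dict[tuple[str, str], list[int]] = {}
    carried: dict[str, dict[str, dict[int, set[str]]]] = {
        s: {} for s in samples
    }
    for rec in records:
        for s in samples:
            gt = rec.genotypes.get(s, (None, None))
            alt_ids = {i for i in gt if i is not None and i > 0}
            if not alt_ids:
                continue
            positions.setdefault((s, rec.chrom), []).append(rec.pos)
            site = carried[s].setdefault(rec.chrom, {})
            site[rec.pos] = {rec.alts[i - 1] for i in alt_ids}

    blocks_by_cultivar: dict[str, list[VariationBlock]] = {}
    for s in samples:
        blocks: list[VariationBlock] = []
        for chrom, length in chrom_lengths.items():
            blocks.extend(
                segment_variation_blocks(
                    sorted(positions.get((s, chrom), [])),
                    length,
                    seg_params,
                    chrom=chrom,
                    cultivar=s,
                )
            )
        blocks_by_cultivar[s] = blocks

    dense_blocks: list[VariationBlock] = []
    variant_sets: list[set[tuple[int, str]]] = []
    for s in samples:
        for b in blocks_by_cultivar[s]:
            if b.klass != DENSE:
                continue
            dense_blocks.append(b)
            site = carried[s].get(b.chrom, {})
            variant_sets.append(
                {
                    (pos, alt)
                    for pos, alts in site.items()
                    if b.start <= pos <= b.end
                    for alt in alts
                }
            )
    typing = assign_block_types(dense_blocks, variant_sets, typing_params)

    dvb_loci = merge_dense_loci(blocks_by_cultivar)
    candidates = extract_candidate_indels(
        records, dvb_loci, min_size=min_indel, max_size=max_indel
    )

    # band patterns per cultivar from genotype allele lengths
    rec_by_site = {(r.chrom, r.pos): r for r in records}
    for cand in candidates:
        rec = rec_by_site[(cand.chrom, cand.pos)]
        cand.flank_left, cand.flank_right = default_flanks(cand.ref_length)
        for s in samples:
            gt = rec.genotypes.get(s, (None, None))
            if gt[0] is None or gt[1] is None:
                cand.patterns[s] = MISSING
                continue
            a, b = sorted(str(rec.allele_length(i)) for i in gt)
            cand.patterns[s] = a if a == b else f"{a}/{b}"
    panel = select_markers(
        candidates,
        per_dvb_quota=per_dvb_quota,
        size_window=amplicon_window,
        max_missing_frac=max_missing_frac,
    )

    marker_ids = panel.marker_ids
    data = pd.DataFrame.from_dict(
        {
            s: [m.patterns.get(s, MISSING) for m in panel.markers]
            for s in samples
        },
        orient="index",
        columns=marker_ids,
    )
    ref_patterns = {
        m.marker_id: str(m.ref_length) for m in panel.markers
    }
    if reference not in data.index:
        data.loc[reference] = [
            ref_patterns[m] for m in marker_ids
        ]
    marker_dvb = {m.marker_id: m.dvb_id for m in panel.markers}
    table = GenotypeTable(data, marker_dvb=marker_dvb, ref_patterns=ref_patterns)
    barcodes = encode_genotypes(table, reference)
    return PanelResult(
        blocks_by_cultivar=blocks_by_cultivar,
        typing=typing,
        dvb_loci=dvb_loci,
        candidates=candidates,
        panel=panel,
        genotype_table=table,
        barcodes=barcodes,
    )
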