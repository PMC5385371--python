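"""dVB-specific InDel marker discovery: candidate extraction, filtering, PIC.

Markers are scored as gel band patterns: alleles are binned by expected
amplicon length in bp, so two alleles of identical length collapse into one
pattern (a gel cannot resolve them).  Discriminating power is measured by
the polymorphism information content

    PIC_i = 1 - sum_j p_ij^2

where ``p_ij`` is the frequency of the j-th band pattern at marker i across
the panel, missing calls dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from vbcode.io_formats import MISSING, VariantRecord
from vbcode.vb_segmentation import DENSE, VariationBlock

DEFAULT_MIN_INDEL = 5
DEFAULT_MAX_INDEL = 20
DEFAULT_AMPLICON_WINDOW = (80, 120)


@dataclass
class InDelCandidate:
    """An InDel locus inside a dense variation block.

    ``allele_lengths`` includes the reference allele first.  ``patterns``
    maps cultivar to its band pattern (an amplicon size, or two sizes joined
    by ``/`` for a heterozygous call, or ``.`` for missing).
    """

    marker_id: str
    chrom: str
    pos: int
    allele_lengths: tuple[int, ...]
    dvb_id: str
    patterns: dict[str, str] = field(default_factory=dict)
    flank_left: int | None = None
    flank_right: int | None = None
    pic: float | None = None

    @property
    def ref_length(self) -> int:
        return self.allele_lengths[0]

    @property
    def indel_size(self) -> int:
        return max(abs(l - self.ref_length) for l in self.allele_lengths[1:])

    def amplicon_sizes(
        self, flank_left: int | None = None, flank_right: int | None = None
    ) -> tuple[int, ...]:
        """Expected amplicon size per allele: left flank + allele + right flank."""
        fl = self.flank_left if flank_left is None else flank_left
        fr = self.flank_right if flank_right is None else flank_right
        if fl is None or fr is None:
            raise ValueError("flank widths not set")
        return tuple(fl + l + fr for l in self.allele_lengths)

    @property
    def allele_size_difference(self) -> int:
        return max(self.allele_lengths) - min(self.allele_lengths)


def default_flanks(ref_length: int, target_ref_amplicon: int = 100) -> tuple[int, int]:
    """Equal flanks centring the InDel so the reference amplicon is ~100 bp.

    Actual primer design is out of scope; this fixes the expected product
    sizes used by the amplicon filter.
    """
    total = max(2, target_ref_amplicon - ref_length)
    left = total // 2
    return left, total - left


def extract_candidate_indels(
    variants: Iterable[VariantRecord],
    dvbs: Sequence[VariationBlock],
    min_size: int = DEFAULT_MIN_INDEL,
    max_size: int = DEFAULT_MAX_INDEL,
) -> list[InDelCandidate]:
    """Keep InDels of ``min_size``..``max_size`` bp lying inside dense blocks.

    SNVs and variants in sparse blocks are excluded.  ``dvbs`` may mix block
    classes; only dense ones host candidates.  The host dVB id is the dense
    block's type label when set, else its coordinates.
    """
    dense = sorted(
        (b for b in dvbs if b.klass == DENSE), key=lambda b: (b.chrom, b.start)
    )
    by_chrom: dict[str, list[VariationBlock]] = {}
    for b in dense:
        by_chrom.setdefault(b.chrom, []).append(b)

    out: list[InDelCandidate] = []
    for rec in variants:
        if not rec.is_indel:
            continue
        if not (min_size <= rec.indel_size <= max_size):
            continue
        host = None
        for b in by_chrom.get(rec.chrom, ()):
            if b.start <= rec.pos <= b.end:
                host = b
                break
        if host is None:
            continue
        if host.type_label is not None:
            dvb_id = f"dVB{host.type_label}"
        else:
            dvb_id = f"{host.chrom}:{host.start}-{host.end}"
        out.append(
            InDelCandidate(
                marker_id=f"{rec.chrom}_{rec.pos}",
                chrom=rec.chrom,
                pos=rec.pos,
                allele_lengths=(len(rec.ref),)
                + tuple(len(a) for a in rec.alts),
                dvb_id=dvb_id,
            )
        )
    return out


@dataclass(frozen=True)
class AmpliconDecision:
    keep: bool
    sizes: tuple[int, ...]


def amplicon_filter(
    candidate: InDelCandidate,
    flank_left: int,
    flank_right: int,
    min_len: int = DEFAULT_AMPLICON_WINDOW[0],
    max_len: int = DEFAULT_AMPLICON_WINDOW[1],
) -> AmpliconDecision:
    """Keep a candidate iff every allele's expected amplicon is in range.

    Short products (80–120 bp by default) resolve small length differences
    cleanly on agarose gels, which is what makes these markers scorable
    without sequencing.
    """
    if flank_left < 1 or flank_right < 1:
        raise ValueError("flanks must be >= 1 bp")
    sizes = candidate.amplicon_sizes(flank_left, flank_right)
    keep = all(min_len <= s <= max_len for s in sizes)
    return AmpliconDecision(keep=keep, sizes=sizes)


def pic(pattern_counts: Sequence[int]) -> float:
    """Polymorphism information content, ``1 - sum of squared frequencies``.

    ``pattern_counts`` are non-negative tallies per band pattern with missing
    calls already excluded.  Bounded by ``1 - 1/n`` for n patterns (0.5 for
    a biallelic marker).  Report rounded to two decimals by convention.
    """
    counts = list(pattern_counts)
    if any(c < 0 for c in counts):
        raise ValueError("pattern counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all pattern counts are zero")
    return 1.0 - sum((c / total) ** 2 for c in counts)


def pattern_counts_from_calls(calls: Iterable[str]) -> dict[str, int]:
    """Tally band patterns from per-cultivar calls.

    A heterozygous ``x/y`` call contributes one count to each of its two
    patterns; missing calls are dropped (not imputed).
    """
    counts: dict[str, int] = {}
    for call in calls:
        if call == MISSING:
            continue
        for p in call.split("/"):
            counts[p] = counts.get(p, 0) + 1
    return counts


@dataclass
class MarkerPanel:
    """Ranked marker selection with a gap report of uncovered dVBs."""

    markers: list[InDelCandidate]
    uncovered_dvbs: list[str]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]


def select_markers(
    candidates: Sequence[InDelCandidate],
    per_dvb_quota: int = 1,
    size_window: tuple[int, int] = DEFAULT_AMPLICON_WINDOW,
    max_missing_frac: float = 0.10,
    per_chrom_cap: int | None = None,
) -> MarkerPanel:
    """Select up to ``per_dvb_quota`` markers per dVB type.

    Candidates must carry ``patterns``; flanks default to centring the InDel
    in a ~100 bp reference amplicon.  Within a dVB candidates are ranked by
    (PIC desc, allele-size difference desc, position asc).  Only candidates
    whose every amplicon falls inside ``size_window`` are eligible, and —
    as a panel-computable proxy for genotyping success — candidates missing
    in more than ``max_missing_frac`` of cultivars are dropped.  Output is
    deterministic for fixed input and stable under candidate order shuffling.
    """
    eligible_by_dvb: dict[str, list[InDelCandidate]] = {}
    all_dvbs: list[str] = []
    for cand in candidates:
        if cand.dvb_id not in all_dvbs:
            all_dvbs.append(cand.dvb_id)
        if cand.flank_left is None or cand.flank_right is None:
            cand.flank_left, cand.flank_right = default_flanks(cand.ref_length)
        decision = amplicon_filter(
            cand, cand.flank_left, cand.flank_right, *size_window
        )
        if not decision.keep:
            continue
        calls = list(cand.patterns.values())
        if not calls:
            continue
        n_missing = sum(1 for c in calls if c == MISSING)
        if n_missing / len(calls) > max_missing_frac:
            continue
        counts = pattern_counts_from_calls(calls)
        if not counts:
            continue
        cand.pic = pic(list(counts.values()))
        eligible_by_dvb.setdefault(cand.dvb_id, []).append(cand)

    selected: list[InDelCandidate] = []
    covered: set[str] = set()
    for dvb_id, cands in eligible_by_dvb.items():
        cands.sort(key=lambda c: (-c.pic, -c.allele_size_difference, c.pos))
        selected.extend(cands[:per_dvb_quota])
        covered.add(dvb_id)

    selected.sort(key=lambda c: (c.chrom, c.pos))
    if per_chrom_cap is not None:
        by_chrom: dict[str, list[InDelCandidate]] = {}
        for m in selected:
            by_chrom.setdefault(m.chrom, []).append(m)
        capped: list[InDelCandidate] = []
        for chrom in by_chrom:
            ranked = sorted(
                by_chrom[chrom],
                key=lambda c: (-(c.pic or 0.0), -c.allele_size_difference, c.pos),
            )[:per_chrom_cap]
            capped.extend(ranked)
        selected = sorted(capped, key=lambda c: (c.chrom, c.pos))

    uncovered = [d for d in all_dvbs if d not in covered]
    return MarkerPanel(markers=selected, uncovered_dvbs=uncovered)
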