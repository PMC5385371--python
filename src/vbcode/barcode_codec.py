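"""Barcode encoding of cultivar genotypes relative to a reference genome.

Each marker call is reduced to one code: ``a`` (white) when the band
pattern equals the reference cultivar's, ``b`` (black) for the most common
alternative pattern, ``c`` for any further (third) allele, ``h`` (green)
for a heterozygous call, and ``.`` for missing.  A cultivar's ordered codes
form its 1D barcode; wrapping them one row per chromosome gives the 2D
barcode.
"""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from PIL import Image, PngImagePlugin

from vbcode.io_formats import MISSING, GenotypeTable

CODE_ALPHABET = ("a", "b", "c", "h", MISSING)

# RGB palette; distinct colours so rendered barcodes decode losslessly
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "a": (255, 255, 255),  # white: same as reference
    "b": (0, 0, 0),  # black: different from reference
    "c": (0, 90, 255),  # third allele
    "h": (0, 170, 0),  # green: heterozygous
    MISSING: (128, 128, 128),
    "pad": (210, 210, 210),
}


class PanelMismatchError(ValueError):
    """Barcodes from different marker panels cannot be compared."""


def _panel_checksum(marker_ids: Sequence[str]) -> str:
    digest = hashlib.sha1("\t".join(marker_ids).encode()).hexdigest()
    return digest[:8]


@dataclass(frozen=True)
class BarcodeRow:
    """One cultivar's barcode: ordered codes plus the panel checksum."""

    cultivar: str
    codes: str
    checksum: str

    def __post_init__(self) -> None:
        bad = set(self.codes) - set(CODE_ALPHABET)
        if bad:
            raise ValueError(f"invalid barcode codes: {sorted(bad)}")


class BarcodeMatrix:
    """Cultivar x marker grid of codes over the alphabet ``{a,b,c,h,.}``.

    Markers are ordered genomically (chromosome, position).  The panel
    checksum, derived from the marker id list, guards against silently
    comparing barcodes built on different panels.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        marker_pos: Mapping[str, tuple[str, int]] | None = None,
        marker_dvb: Mapping[str, str] | None = None,
        reference: str | None = None,
    ) -> None:
        bad = set("".join("".join(row) for row in data.values)) - set(
            CODE_ALPHABET
        )
        if bad:
            raise ValueError(f"invalid barcode codes: {sorted(bad)}")
        self.marker_pos = dict(marker_pos or {})
        if self.marker_pos:
            order = sorted(data.columns, key=lambda m: self.marker_pos[m])
            data = data[order]
        self.data = data
        self.marker_dvb = dict(marker_dvb or {})
        self.reference = reference
        self.checksum = _panel_checksum(list(data.columns))

    @property
    def cultivars(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def row(self, cultivar: str) -> BarcodeRow:
        return BarcodeRow(
            cultivar=cultivar,
            codes="".join(self.data.loc[cultivar]),
            checksum=self.checksum,
        )

    def chromosome_layout(self) -> list[tuple[str, int]]:
        """Ordered (chromosome, n_markers) runs, for 2D wrapping."""
        runs: list[tuple[str, int]] = []
        for m in self.markers:
            chrom = self.marker_pos.get(m, ("?", 0))[0]
            if runs and runs[-1][0] == chrom:
                runs[-1] = (chrom, runs[-1][1] + 1)
            else:
                runs.append((chrom, 1))
        return runs

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#checksum={self.checksum}\n")
            if self.reference:
                fh.write(f"#reference={self.reference}\n")
            fh.write("cultivar\t" + "\t".join(self.markers) + "\n")
            fh.write(
                "#chrom\t"
                + "\t".join(
                    self.marker_pos.get(m, ("?", 0))[0] for m in self.markers
                )
                + "\n"
            )
            fh.write(
                "#pos\t"
                + "\t".join(
                    str(self.marker_pos.get(m, ("?", 0))[1])
                    for m in self.markers
                )
                + "\n"
            )
            for cultivar in self.cultivars:
                fh.write(
                    f"{cultivar}\t" + "\t".join(self.data.loc[cultivar]) + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "BarcodeMatrix":
        reference = None
        markers: list[str] = []
        chroms: list[str] = []
        poss: list[int] = []
        rows: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#reference="):
                    reference = line.split("=", 1)[1]
                elif line.startswith("#checksum="):
                    continue
                elif line.startswith("cultivar\t"):
                    markers = line.split("\t")[1:]
                elif line.startswith("#chrom\t"):
                    chroms = line.split("\t")[1:]
                elif line.startswith("#pos\t"):
                    poss = [int(p) for p in line.split("\t")[1:]]
                elif line:
                    parts = line.split("\t")
                    rows[parts[0]] = parts[1:]
        data = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
        marker_pos = None
        if chroms and poss:
            marker_pos = {
                m: (c, p) for m, c, p in zip(markers, chroms, poss)
            }
        return cls(data, marker_pos=marker_pos, reference=reference)


def encode_genotypes(
    table: GenotypeTable, reference_cultivar: str
) -> BarcodeMatrix:
    """Encode a genotype table as barcodes relative to one cultivar.

    Per marker, the reference cultivar's pattern becomes ``a``; alternative
    patterns are ranked by panel frequency, the most common becoming ``b``
    and any further pattern ``c``.  A call containing two distinct patterns
    is ``h``; missing propagates as ``.``.  When the reference cultivar's
    own call is missing, the column is keyed to the table's declared
    reference-genome pattern instead (with a warning).
    """
    if reference_cultivar not in table.cultivars:
        raise KeyError(f"reference cultivar {reference_cultivar!r} not in table")

    codes = pd.DataFrame(
        index=table.data.index, columns=table.data.columns, dtype=object
    )
    marker_pos: dict[str, tuple[str, int]] = {}
    for marker in table.markers:
        ref_call = table.cell(reference_cultivar, marker)
        if ref_call == MISSING or "/" in ref_call:
            declared = table.ref_patterns.get(marker)
            if declared is None:
                raise ValueError(
                    f"reference call missing at {marker} and no declared "
                    "reference pattern available"
                )
            warnings.warn(
                f"reference cultivar missing at {marker}; using declared "
                f"reference pattern {declared!r}",
                stacklevel=2,
            )
            ref_pattern = declared
        else:
            ref_pattern = ref_call

        # rank alternative patterns by panel frequency (het calls count both)
        freq: dict[str, int] = {}
        for call in table.data[marker]:
            if call == MISSING:
                continue
            for p in call.split("/"):
                if p != ref_pattern:
                    freq[p] = freq.get(p, 0) + 1
        ranked = sorted(freq, key=lambda p: (-freq[p], p))
        b_pattern = ranked[0] if ranked else None

        column = []
        for cultivar in table.cultivars:
            call = table.cell(cultivar, marker)
            if call == MISSING:
                column.append(MISSING)
            elif "/" in call:
                left, _, right = call.partition("/")
                column.append("h" if left != right else _code(left, ref_pattern, b_pattern))
            else:
                column.append(_code(call, ref_pattern, b_pattern))
        codes[marker] = column
        if "_" in marker:
            chrom, _, pos = marker.rpartition("_")
            if pos.isdigit():
                marker_pos[marker] = (chrom, int(pos))

    return BarcodeMatrix(
        codes,
        marker_pos=marker_pos or None,
        marker_dvb=table.marker_dvb,
        reference=reference_cultivar,
    )


def _code(pattern: str, ref_pattern: str, b_pattern: str | None) -> str:
    if pattern == ref_pattern:
        return "a"
    if b_pattern is None or pattern == b_pattern:
        return "b"
    return "c"


def barcode_string(row: BarcodeRow) -> str:
    """Compact text form ``checksum|cultivar|codes``, round-trippable."""
    return f"{row.checksum}|{row.cultivar}|{row.codes}"


def parse_barcode(text: str, expected_checksum: str | None = None) -> BarcodeRow:
    """Inverse of :func:`barcode_string`.

    With ``expected_checksum`` given, a mismatch raises
    :class:`PanelMismatchError` — codes from different marker panels must not
    be silently compared.
    """
    if not text:
        raise ValueError("empty barcode string")
    parts = text.split("|")
    if len(parts) != 3:
        raise ValueError(f"malformed barcode string: {text!r}")
    checksum, cultivar, codes = parts
    if expected_checksum is not None and checksum != expected_checksum:
        raise PanelMismatchError(
            f"panel mismatch: {checksum} != {expected_checksum}"
        )
    return BarcodeRow(cultivar=cultivar, codes=codes, checksum=checksum)


def render_ascii(row: BarcodeRow) -> str:
    """One glyph per marker: ``#``=b, ``.``=a, ``H``=h, ``C``=c, `` ``=missing."""
    glyph = {"a": ".", "b": "#", "c": "C", "h": "H", MISSING: " "}
    return "".join(glyph[c] for c in row.codes)


def render_barcode(
    row: BarcodeRow,
    style: str = "1d",
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    chromosome_layout: Sequence[tuple[str, int]] | None = None,
    cell_px: int = 8,
    path: str | os.PathLike | None = None,
) -> Image.Image:
    """Render a barcode row as a PNG-able image.

    ``1d`` draws one stripe per marker in genomic order (white = same as
    reference, black = different, green = heterozygous).  ``2d`` wraps the
    markers into one row per chromosome (``chromosome_layout`` gives the
    (chromosome, n_markers) runs), padding trailing cells grey.  Layout
    metadata is embedded in the PNG text chunk so :func:`decode_barcode`
    recovers the exact code string.
    """
    palette = dict(palette or DEFAULT_PALETTE)
    codes = row.codes
    if not codes:
        raise ValueError("cannot render an empty barcode row")
    style = style.lower()
    if style == "1d":
        rows = [codes]
    elif style == "2d":
        if chromosome_layout is None:
            raise ValueError("2d rendering needs a chromosome layout")
        rows = []
        cursor = 0
        for _chrom, n in chromosome_layout:
            rows.append(codes[cursor : cursor + n])
            cursor += n
        if cursor != len(codes):
            raise ValueError("chromosome layout does not cover all markers")
    else:
        raise ValueError(f"unknown style {style!r}")

    width = max(len(r) for r in rows)
    img = Image.new("RGB", (width * cell_px, len(rows) * cell_px))
    px = img.load()
    for y, rcodes in enumerate(rows):
        for x in range(width):
            colour = palette[rcodes[x]] if x < len(rcodes) else palette["pad"]
            for dy in range(cell_px):
                for dx in range(cell_px):
                    px[x * cell_px + dx, y * cell_px + dy] = colour

    meta = PngImagePlugin.PngInfo()
    meta.add_text("vbcode:cultivar", row.cultivar)
    meta.add_text("vbcode:checksum", row.checksum)
    meta.add_text("vbcode:cell_px", str(cell_px))
    meta.add_text("vbcode:row_lengths", ",".join(str(len(r)) for r in rows))
    if path is not None:
        img.save(os.fspath(path), pnginfo=meta)
    else:
        img.info["vbcode:cultivar"] = row.cultivar
        img.info["vbcode:checksum"] = row.checksum
        img.info["vbcode:cell_px"] = str(cell_px)
        img.info["vbcode:row_lengths"] = ",".join(str(len(r)) for r in rows)
    return img


def decode_barcode(
    source: Image.Image | str | os.PathLike,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
) -> BarcodeRow:
    """Recover the code string from a rendered barcode image."""
    palette = dict(palette or DEFAULT_PALETTE)
    colour_to_code = {v: k for k, v in palette.items() if k != "pad"}
    img = source if isinstance(source, Image.Image) else Image.open(source)
    info = img.info
    cell_px = int(info["vbcode:cell_px"])
    row_lengths = [int(n) for n in str(info["vbcode:row_lengths"]).split(",")]
    px = img.convert("RGB").load()
    codes = []
    half = cell_px // 2
    for y, n in enumerate(row_lengths):
        for x in range(n):
            colour = px[x * cell_px + half, y * cell_px + half]
            codes.append(colour_to_code[colour])
    return BarcodeRow(
        cultivar=str(info["vbcode:cultivar"]),
        codes="".join(codes),
        checksum=str(info["vbcode:checksum"]),
    )
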