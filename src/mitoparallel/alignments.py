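"""Structure-annotated rRNA alignment input.

The alignment itself is gapped FASTA; interaction sites arrive as a
tab-separated table of 1-based column pairs with one of four class labels;
sequence group labels (bacterial / mitochondrial / plastid, or any other
scheme) come from a two-column TSV keyed by sequence id.
"""
from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .types import SITE_CLASSES, InteractionSite, StructureAlignment

TextOrPath = Union[str, Path]


class AlignmentParseError(ValueError):
    pass


def _read_text(source: TextOrPath) -> str:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        return Path(source).read_text()
    return str(source)


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("T", "U")


def parse_sites_table(text: str) -> list[InteractionSite]:
    """Parse a TSV of (col_i, col_j, site_class); a header line is allowed."""
    sites: list[InteractionSite] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AlignmentParseError(
                f"site table line {lineno}: expected 3 tab-separated columns"
            )
        if lineno == 1 and not parts[0].lstrip("-").isdigit():
            continue  # header
        try:
            col_i, col_j = int(parts[0]), int(parts[1])
        except ValueError as err:
            raise AlignmentParseError(
                f"site table line {lineno}: non-integer column index"
            ) from err
        label = parts[2].strip()
        if label not in SITE_CLASSES:
            raise AlignmentParseError(
                f"site table line {lineno}: unknown site class {label!r}; "
                f"allowed: {', '.join(SITE_CLASSES)}"
            )
        if col_i > col_j:
            col_i, col_j = col_j, col_i
        sites.append(InteractionSite(col_i=col_i, col_j=col_j, site_class=label))
    return sites


def parse_structure_alignment(
    seq_source: TextOrPath,
    sites_source: TextOrPath,
    groups: Optional[Union[TextOrPath, dict[str, str]]] = None,
) -> StructureAlignment:
    """Assemble a :class:`StructureAlignment` from FASTA + site table (+ groups).

    T is normalized to U and case is folded; sequences must be equal length;
    every site must reference columns inside the alignment.
    """
    seq_text = _read_text(seq_source)
    records = list(SeqIO.parse(io.StringIO(seq_text), "fasta"))
    if not records:
        raise AlignmentParseError("no sequences in alignment input")
    seq_ids = [r.id for r in records]
    sequences = [_normalize_seq(str(r.seq)) for r in records]
    widths = {len(s) for s in sequences}
    if len(widths) > 1:
        raise AlignmentParseError(
            f"ragged alignment: sequence lengths {sorted(widths)}"
        )
    width = widths.pop()

    sites = parse_sites_table(_read_text(sites_source))
    for s in sites:
        if s.col_j > width:
            raise AlignmentParseError(
                f"site ({s.col_i},{s.col_j},{s.site_class}) outside alignment "
                f"of width {width}"
            )

    group_map: dict[str, str] = {}
    if isinstance(groups, dict):
        group_map = dict(groups)
    elif groups is not None:
        for lineno, line in enumerate(_read_text(groups).splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AlignmentParseError(
                    f"group table line {lineno}: expected (seq_id, group)"
                )
            if lineno == 1 and parts[0] in ("seq_id", "id", "sequence"):
                continue
            group_map[parts[0]] = parts[1]
    seq_groups = [group_map.get(sid, "all") for sid in seq_ids]

    return StructureAlignment(
        sequences=sequences,
        seq_ids=seq_ids,
        seq_groups=seq_groups,
        sites=sites,
    )
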