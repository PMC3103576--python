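"""Annotated multiple alignments and order/disorder masks.

Alignments are read with Biopython (FASTA or relaxed PHYLIP) and held as an
integer-coded row matrix.  Disorder annotations arrive either as DisProt-style
1-based inclusive intervals on the *ungapped* reference sequence or as an
inline mask string, and are projected onto alignment columns through the
reference row: columns where the reference is gapped carry no annotation and
are excluded from estimation and testing.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from ._util import path_or_text as _path_or_text

from .alphabet import AMINO, GAP, MISSING, Alphabet

__all__ = [
    "ORDERED",
    "DISORDERED",
    "UNANNOTATED",
    "AnnotatedAlignment",
    "RegionAnnotation",
    "read_alignment",
    "read_annotated_alignment",
    "read_region_tsv",
    "project_annotation",
    "split_by_mask",
    "merge_columns",
    "bootstrap_columns",
    "jackknife_rows",
    "pairwise_pam_distance_filter",
]

#: Column mask labels.
ORDERED, DISORDERED, UNANNOTATED = 0, 1, 2

MASK_CHARS = {ORDERED: "O", DISORDERED: "D", UNANNOTATED: "."}


@dataclass(eq=False)
class AnnotatedAlignment:
    """Aligned rows plus a per-column order/disorder label.

    ``codes`` is (n_rows, n_cols) int8 with residue indices and the GAP /
    MISSING sentinels; ``mask`` is per-column in {ORDERED, DISORDERED,
    UNANNOTATED}.
    """

    names: list[str]
    codes: np.ndarray
    mask: np.ndarray = None
    group_id: str = ""
    reference_row: str | None = None
    alphabet: Alphabet = AMINO
    column_indices: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (rows x columns)")
        if len(self.names) != self.codes.shape[0]:
            raise ValueError("row name count does not match matrix")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row names")
        if self.codes.shape[0] < 2:
            raise ValueError("alignment needs at least 2 rows")
        if self.mask is None:
            self.mask = np.full(self.codes.shape[1], UNANNOTATED, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.mask.shape[0] != self.codes.shape[1]:
            raise ValueError("mask length does not match alignment length")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_cols(self) -> int:
        return self.codes.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.codes[self.names.index(name)]

    def sequences(self) -> dict[str, str]:
        return {n: self.alphabet.decode(r) for n, r in zip(self.names, self.codes)}

    def mask_string(self) -> str:
        return "".join(MASK_CHARS[int(m)] for m in self.mask)

    def to_fasta(self, path=None) -> str:
        out = io.StringIO()
        for name, row in zip(self.names, self.codes):
            out.write(f">{name}\n{self.alphabet.decode(row)}\n")
        text = out.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class RegionAnnotation:
    """Disordered intervals, 1-based inclusive on the ungapped reference."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        merged = merge_intervals(self.intervals)
        object.__setattr__(self, "intervals", merged)

    def covers(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.intervals)


def merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if a < 1 or b < a:
            raise ValueError(f"bad interval ({a}, {b}): 1-based inclusive required")
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


# ---------------------------------------------------------------------------
# readers


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return "fasta" if line.lstrip().startswith(">") else "phylip-relaxed"
    raise ValueError("empty alignment file")


def read_alignment(
    path_or_text, alphabet: Alphabet = AMINO, group_id: str = ""
) -> AnnotatedAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment (format sniffed)."""
    text = _path_or_text(path_or_text)
    if not group_id and text != str(path_or_text):
        group_id = Path(str(path_or_text)).stem
    fmt = _sniff_format(text)
    msa = AlignIO.read(io.StringIO(text), fmt)
    names = [rec.id for rec in msa]
    codes = np.vstack([alphabet.encode(str(rec.seq)) for rec in msa])
    return AnnotatedAlignment(
        names=names, codes=codes, group_id=group_id, alphabet=alphabet
    )


def read_region_tsv(path_or_text, group_id: str | None = None) -> RegionAnnotation:
    """Read disordered intervals from TSV: ``start<TAB>end`` or
    ``group_id<TAB>start<TAB>end`` rows (filtered on group_id when given)."""
    text = _path_or_text(path_or_text)
    intervals = []
    for line in text.splitlines():
        parts = line.strip().split("\t")
        if not line.strip() or line.startswith("#"):
            continue
        if len(parts) == 2:
            intervals.append((int(parts[0]), int(parts[1])))
        elif len(parts) == 3:
            if group_id is None or parts[0] == group_id:
                intervals.append((int(parts[1]), int(parts[2])))
        else:
            raise ValueError(f"bad mask TSV line: {line!r}")
    return RegionAnnotation(intervals=tuple(intervals))


def project_annotation(
    aln: AnnotatedAlignment,
    annotation: "RegionAnnotation | str",
    reference_name: str,
) -> AnnotatedAlignment:
    """Project a reference-sequence annotation onto alignment columns.

    Each column whose reference residue falls inside a disordered interval is
    labelled DISORDERED; other reference-covered columns ORDERED; columns
    where the reference is gapped UNANNOTATED.  An inline mask string of
    O/D characters (ungapped-reference length) is accepted in place of
    intervals.
    """
    if reference_name not in aln.names:
        raise ValueError(f"reference row {reference_name!r} not in alignment")
    ref = aln.row(reference_name)
    ungapped_len = int(np.sum(ref != GAP))

    if isinstance(annotation, str):
        if len(annotation) != ungapped_len:
            raise ValueError(
                f"mask string length {len(annotation)} != ungapped reference "
                f"length {ungapped_len}"
            )
        disordered = {
            i + 1 for i, c in enumerate(annotation.upper()) if c == "D"
        }
        if not set(annotation.upper()) <= {"O", "D"}:
            raise ValueError("inline mask may contain only O and D")
    else:
        for a, b in annotation.intervals:
            if b > ungapped_len:
                raise ValueError(
                    f"interval ({a}, {b}) beyond reference length {ungapped_len}"
                )
        disordered = {
            pos for a, b in annotation.intervals for pos in range(a, b + 1)
        }

    mask = np.full(aln.n_cols, UNANNOTATED, dtype=np.int8)
    pos = 0  # 1-based ungapped position of the last reference residue seen
    for col in range(aln.n_cols):
        if ref[col] == GAP:
            continue
        pos += 1
        mask[col] = DISORDERED if pos in disordered else ORDERED
    return AnnotatedAlignment(
        names=list(aln.names),
        codes=aln.codes.copy(),
        mask=mask,
        group_id=aln.group_id,
        reference_row=reference_name,
        alphabet=aln.alphabet,
    )


def read_annotated_alignment(
    alignment_path,
    annotation_path,
    reference_name: str,
    alphabet: Alphabet = AMINO,
    group_id: str = "",
) -> AnnotatedAlignment:
    """Read alignment + annotation and project onto columns (see above)."""
    aln = read_alignment(alignment_path, alphabet=alphabet, group_id=group_id)
    text = _path_or_text(annotation_path)
    stripped = text.strip()
    if stripped and set(stripped.upper()) <= {"O", "D"}:
        annotation: RegionAnnotation | str = stripped
    else:
        annotation = read_region_tsv(text, group_id=aln.group_id or None)
    return project_annotation(aln, annotation, reference_name)


# ---------------------------------------------------------------------------
# mask-driven splitting and resampling


def split_by_mask(
    aln: AnnotatedAlignment,
) -> tuple[AnnotatedAlignment, AnnotatedAlignment]:
    """Column-disjoint (ordered, disordered) sub-alignments.

    Unannotated columns are dropped.  An empty class yields a 0-column
    sub-alignment; ``column_indices`` records the source columns so the
    annotated part of the original can be reassembled with
    :func:`merge_columns`.
    """
    parts = []
    for label in (ORDERED, DISORDERED):
        idx = np.flatnonzero(aln.mask == label)
        parts.append(
            AnnotatedAlignment(
                names=list(aln.names),
                codes=aln.codes[:, idx],
                mask=np.full(idx.size, label, dtype=np.int8),
                group_id=aln.group_id,
                reference_row=aln.reference_row,
                alphabet=aln.alphabet,
                column_indices=idx,
            )
        )
    return parts[0], parts[1]


def merge_columns(
    parts: list[AnnotatedAlignment], n_cols: int | None = None
) -> AnnotatedAlignment:
    """Reassemble sub-alignments (carrying ``column_indices``) by position."""
    if not parts or any(p.column_indices is None for p in parts):
        raise ValueError("parts must carry column_indices")
    all_idx = np.concatenate([p.column_indices for p in parts])
    total = int(all_idx.max()) + 1 if n_cols is None else n_cols
    codes = np.full((parts[0].n_rows, total), GAP, dtype=np.int8)
    mask = np.full(total, UNANNOTATED, dtype=np.int8)
    for p in parts:
        codes[:, p.column_indices] = p.codes
        mask[p.column_indices] = p.mask
    keep = np.sort(all_idx)
    return AnnotatedAlignment(
        names=list(parts[0].names),
        codes=codes[:, keep],
        mask=mask[keep],
        group_id=parts[0].group_id,
        reference_row=parts[0].reference_row,
        alphabet=parts[0].alphabet,
        column_indices=keep,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bootstrap_columns(aln: AnnotatedAlignment, seed) -> AnnotatedAlignment:
    """Resample columns with replacement (mask resampled jointly)."""
    rng = _as_rng(seed)
    idx = rng.integers(0, aln.n_cols, size=aln.n_cols)
    return AnnotatedAlignment(
        names=list(aln.names),
        codes=aln.codes[:, idx],
        mask=aln.mask[idx],
        group_id=aln.group_id,
        reference_row=aln.reference_row,
        alphabet=aln.alphabet,
    )


def jackknife_rows(
    aln: AnnotatedAlignment, drop_fraction: float, seed
) -> AnnotatedAlignment:
    """Remove a random fixed fraction of rows without replacement."""
    rng = _as_rng(seed)
    n_drop = int(round(drop_fraction * aln.n_rows))
    if drop_fraction < 0 or aln.n_rows - n_drop < 2:
        raise ValueError(
            f"drop_fraction {drop_fraction} leaves fewer than 2 of "
            f"{aln.n_rows} rows"
        )
    drop = set(rng.choice(aln.n_rows, size=n_drop, replace=False).tolist())
    keep = [i for i in range(aln.n_rows) if i not in drop]
    return AnnotatedAlignment(
        names=[aln.names[i] for i in keep],
        codes=aln.codes[keep],
        mask=aln.mask.copy(),
        group_id=aln.group_id,
        reference_row=aln.reference_row if aln.reference_row and aln.names.index(aln.reference_row) in keep else None,
        alphabet=aln.alphabet,
    )


def pairwise_pam_distance_filter(
    aln: AnnotatedAlignment,
    reference_name: str,
    max_pam: float,
    distance_fn,
) -> AnnotatedAlignment:
    """Optional pre-filter: keep rows within ``max_pam`` PAM of the reference.

    ``distance_fn(row_a_codes, row_b_codes) -> float`` supplies the distance
    in substitutions/site (multiplied by 100 to read as PAM).
    """
    ref = aln.row(reference_name)
    keep = []
    for i, name in enumerate(aln.names):
        if name == reference_name:
            keep.append(i)
            continue
        d = 100.0 * distance_fn(ref, aln.codes[i])
        if d <= max_pam:
            keep.append(i)
    if len(keep) < 2:
        warnings.warn("PAM filter left fewer than 2 rows; returning unfiltered")
        return aln
    return AnnotatedAlignment(
        names=[aln.names[i] for i in keep],
        codes=aln.codes[keep],
        mask=aln.mask.copy(),
        group_id=aln.group_id,
        reference_row=reference_name,
        alphabet=aln.alphabet,
    )
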