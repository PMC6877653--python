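"""Mismatch-tolerant epitope conservancy computation.

An epitope peptide of length L is slid ungapped over every length-L
window of a homolog sequence; the minimum Hamming distance over all
windows is the epitope's mismatch count in that homolog. An epitope
counts as conserved in a homolog when that minimum is at or below a
mismatch tolerance (default 2 substitutions). The ambiguity letter X
scores as a mismatch against everything, including X.

An optional MSA-anchored mode maps the epitope's reference columns
through a multiple alignment and counts mismatches in the aligned
columns (gaps count as mismatches); it exists for sensitivity analysis
and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from epiconserve.io_core import (
    EpitopeRecord,
    ProteinEntry,
    SEQUENCE_AA,
    STANDARD_AA,
    ValidationError,
)

DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped match of one epitope in one homolog.

    ``min_mismatches`` and ``best_offset`` are ``None`` when the homolog
    is shorter than the epitope (no window exists); ``best_offset`` is
    the 1-based start of the best window, ties broken to the smallest
    offset.
    """

    epitope_id: str
    accession: str
    length: int
    min_mismatches: int | None
    best_offset: int | None

    @property
    def identity(self) -> float | None:
        if self.min_mismatches is None:
            return None
        return (self.length - self.min_mismatches) / self.length

    def conserved(self, max_mismatch: int) -> bool:
        return self.min_mismatches is not None and self.min_mismatches <= max_mismatch


@dataclass
class ConservationMatrix:
    """Epitopes x homologs minimum-mismatch counts.

    ``data`` is a float DataFrame (rows = epitope ids, columns =
    accessions) with NaN as the no-window sentinel; ``epitope_lengths``
    records each epitope's length for downstream imputation.
    """

    data: pd.DataFrame
    epitope_lengths: dict[str, int]

    @property
    def epitope_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "epitope_id"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")

    @classmethod
    def from_tsv(cls, path, epitope_lengths: dict[str, int] | None = None) -> "ConservationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="epitope_id", na_values=["NA"])
        return cls(data=df.astype(float), epitope_lengths=dict(epitope_lengths or {}))


def _validate_alphabet(s: str, what: str, allow_x: bool) -> str:
    s = s.upper()
    allowed = SEQUENCE_AA if allow_x else STANDARD_AA
    bad = set(s) - allowed
    if bad:
        raise ValidationError(f"{what}: invalid residue letters {sorted(bad)}")
    return s


def min_mismatch_scan(
    peptide: str,
    sequence: str,
    epitope_id: str = "",
    accession: str = "",
) -> MatchResult:
    """Minimum Hamming distance of ``peptide`` over all ungapped windows.

    Returns a no-window result (``min_mismatches`` None) when the
    protein is shorter than the peptide. X never matches any letter.
    """
    peptide = _validate_alphabet(peptide, "peptide", allow_x=False)
    sequence = _validate_alphabet(sequence, "sequence", allow_x=True)
    L = len(peptide)
    if L < 1:
        raise ValidationError("peptide must have length >= 1")
    if len(sequence) < L:
        return MatchResult(epitope_id, accession, L, None, None)
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    pep = np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, L)
    # X in the protein mismatches everything (the peptide never carries X)
    matches = (windows == pep) & (windows != ord("X"))
    mismatches = L - matches.sum(axis=1)
    best = int(mismatches.argmin())  # argmin takes the first minimum: smallest offset
    return MatchResult(epitope_id, accession, L, int(mismatches[best]), best + 1)


def msa_anchored_mismatches(
    peptide: str,
    start: int,
    reference_aligned: str,
    target_aligned: str,
) -> int:
    """Mismatch count in the aligned columns covering the epitope span.

    The epitope occupies reference positions ``start .. start+L-1``
    (1-based, ungapped). Those positions are mapped to alignment columns
    through the gapped reference; in each column the target residue is
    compared with the epitope letter, gaps and X counting as mismatches.
    """
    peptide = _validate_alphabet(peptide, "peptide", allow_x=False)
    if len(reference_aligned) != len(target_aligned):
        raise ValidationError("aligned sequences differ in length")
    cols = [i for i, c in enumerate(reference_aligned) if c not in "-."]
    L = len(peptide)
    if start < 1 or start + L - 1 > len(cols):
        raise ValidationError(
            f"epitope span {start}-{start + L - 1} outside ungapped reference "
            f"length {len(cols)}"
        )
    mismatches = 0
    for k in range(L):
        t = target_aligned[cols[start - 1 + k]].upper()
        if t in "-." or t == "X" or t != peptide[k]:
            mismatches += 1
    return mismatches


def conservancy_fraction(
    epitope: EpitopeRecord,
    proteins: Sequence[ProteinEntry],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[float, list[MatchResult]]:
    """Fraction of homologs in which the epitope is conserved.

    A homolog counts as conserved when its best window has at most
    ``max_mismatch`` substitutions; homologs shorter than the epitope
    count as not conserved. The per-homolog results are returned for
    audit.
    """
    if not proteins:
        raise ValidationError("conservancy_fraction: empty protein list")
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    results = [
        min_mismatch_scan(epitope.peptide, p.sequence, epitope.epitope_id, p.accession)
        for p in proteins
    ]
    conserved = sum(r.conserved(max_mismatch) for r in results)
    return conserved / len(results), results


def mismatch_matrix(
    epitopes: Sequence[EpitopeRecord],
    proteins: Sequence[ProteinEntry],
) -> ConservationMatrix:
    """Minimum-mismatch counts for every epitope x homolog pair."""
    if not epitopes or not proteins:
        raise ValidationError("mismatch_matrix: empty input")
    ids = [e.epitope_id for e in epitopes]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate epitope ids {dupes}")
    accs = [p.accession for p in proteins]
    if len(set(accs)) != len(accs):
        dupes = sorted({x for x in accs if accs.count(x) > 1})
        raise ValidationError(f"duplicate accessions {dupes}")
    cells = np.full((len(epitopes), len(proteins)), np.nan)
    for i, e in enumerate(epitopes):
        for j, p in enumerate(proteins):
            r = min_mismatch_scan(e.peptide, p.sequence, e.epitope_id, p.accession)
            if r.min_mismatches is not None:
                cells[i, j] = r.min_mismatches
    data = pd.DataFrame(cells, index=ids, columns=accs)
    return ConservationMatrix(
        data=data, epitope_lengths={e.epitope_id: len(e) for e in epitopes}
    )
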