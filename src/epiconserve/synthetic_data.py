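"""Seeded generator of allergen homolog families with known ground truth.

Emulates the structure of an invertebrate allergen family: an ancestral
sequence with highly conserved N- and C-terminal blocks (as in
tropomyosin), four taxonomic groups of descendant species produced by
independent per-site substitution, mollusc species split into three
classes, and epitopes tiled over the ancestor in the short overlapping
style of experimental peptide libraries.

The module also ships a brute-force truth oracle — a deliberately
separate code path from the conservancy module (pure-Python character
loops, no shared helpers) — so that every pipeline stage can be checked
against independently computed ground truth.

Substitutions are site-independent with no indels, so the ungapped
sliding-window scan is exactly the right matching model; an optional
indel mode exists for robustness exercises and is excluded from
oracle-equivalence guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from epiconserve.io_core import (
    EpitopeRecord,
    GroupConfig,
    GROUPS,
    MOLLUSC_CLASSES,
    ProteinEntry,
    ValidationError,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_SIZES = {"crustacean": 18, "cockroach": 6, "mite": 6, "mollusc": 30}


def _default_rates(value: float) -> dict[str, float]:
    return {g: value for g in GROUPS}


@dataclass
class SimulationParams:
    """Study conditions for one simulated homolog family.

    Defaults: a 284-residue ancestor (the length of shrimp tropomyosin)
    with conserved blocks at both termini; species counts of 18
    crustacean and 30 mollusc (10 per class) as in the published
    homolog sets, with smaller cockroach and mite panels; substitution
    probability 0.3 per site outside conserved blocks and 0 inside, so
    planted conservation is unambiguous; 15-mer epitopes tiled at step
    3, the typical overlapping-peptide-library design.
    """

    ancestor_length: int = 284
    conserved_blocks: tuple[tuple[int, int], ...] = ((1, 42), (243, 284))
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    p_outside: dict[str, float] = field(default_factory=lambda: _default_rates(0.3))
    q_inside: dict[str, float] = field(default_factory=lambda: _default_rates(0.0))
    epitope_lengths: tuple[int, ...] = (15,)
    tile_step: int = 3
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValidationError("ancestor_length must be >= 1")
        for s, e in self.conserved_blocks:
            if not (1 <= s <= e <= self.ancestor_length):
                raise ValidationError(f"block {s}-{e} outside ancestor")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r}")
            if n < 1:
                raise ValidationError(f"group {g!r}: count must be >= 1")
        for g in self.group_sizes:
            p = self.p_outside.get(g)
            q = self.q_inside.get(g)
            if p is None or q is None:
                raise ValidationError(f"group {g!r}: missing substitution rates")
            if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
                raise ValidationError(f"group {g!r}: rates must lie in [0, 1]")
            if q > p:
                raise ValidationError(
                    f"group {g!r}: in-block rate {q} exceeds out-of-block rate {p}"
                )
        if any(L > self.ancestor_length for L in self.epitope_lengths):
            raise ValidationError("epitope length exceeds ancestor length")
        if self.tile_step < 1:
            raise ValidationError("tile_step must be >= 1")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValidationError("indel_rate must lie in [0, 1)")


def divergence_hierarchy_params(**overrides) -> SimulationParams:
    """Preset mirroring the observed cross-reactivity hierarchy.

    Out-of-block divergence increases crustacean < cockroach < mite <
    mollusc, so conservancy falls in that order — useful for relatedness
    and clustering exercises. The base defaults keep a single rate so
    that planted-block contrasts are uniform across groups.
    """
    params = SimulationParams(
        p_outside={"crustacean": 0.05, "cockroach": 0.15, "mite": 0.22, "mollusc": 0.35},
        **overrides,
    )
    return params


@dataclass(frozen=True)
class SimulatedFamily:
    """One simulated homolog family: ancestor, species entries, parameters."""

    ancestor: str
    entries: tuple[ProteinEntry, ...]
    params: SimulationParams

    def group_config(self) -> GroupConfig:
        return GroupConfig.from_entries(self.entries)


def _block_mask(params: SimulationParams) -> np.ndarray:
    mask = np.zeros(params.ancestor_length, dtype=bool)
    for s, e in params.conserved_blocks:
        mask[s - 1 : e] = True
    return mask


def mutate_sequence(sequence: str, rates: np.ndarray | float, rng: np.random.Generator) -> str:
    """Independent per-site substitution; the new residue is uniform over the other 19."""
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    rates = np.broadcast_to(np.asarray(rates, dtype=float), seq.shape)
    hit = rng.random(seq.shape) < rates
    if hit.any():
        alphabet = np.frombuffer(AA.encode("ascii"), dtype=np.uint8)
        current = np.searchsorted(alphabet, seq[hit])
        shift = rng.integers(1, 20, size=hit.sum())
        seq[hit] = alphabet[(current + shift) % 20]
    return seq.tobytes().decode("ascii")


def _apply_indels(sequence: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in sequence:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if r >= rate / 2 and r < rate:
            out.append(AA[rng.integers(0, 20)])  # insertion after the site
    return "".join(out) or sequence[:1]


def simulate_family(
    params: SimulationParams | None = None,
    seed: int | None = None,
    ancestor: str | None = None,
) -> SimulatedFamily:
    """Draw one homolog family, fully reproducible from the seed.

    The ancestor is uniform over the 20 residues unless supplied (an
    explicit ancestor lets callers build hierarchical families by
    pre-diverging group ancestors). Each species is derived
    independently by per-site substitution at the out-of-block rate of
    its group, reduced to the in-block rate inside conserved blocks.
    """
    params = params if params is not None else SimulationParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if ancestor is None:
        ancestor = "".join(
            AA[i] for i in rng.integers(0, 20, size=params.ancestor_length)
        )
    elif len(ancestor) != params.ancestor_length:
        raise ValidationError(
            f"supplied ancestor length {len(ancestor)} != params.ancestor_length "
            f"{params.ancestor_length}"
        )
    mask = _block_mask(params)
    entries = []
    for group in GROUPS:
        n = params.group_sizes.get(group, 0)
        if n == 0:
            continue
        rates = np.where(mask, params.q_inside[group], params.p_outside[group])
        for i in range(n):
            seq = mutate_sequence(ancestor, rates, rng)
            if params.indel_rate > 0:
                seq = _apply_indels(seq, params.indel_rate, rng)
            mollusc_class = (
                MOLLUSC_CLASSES[(3 * i) // n] if group == "mollusc" else None
            )
            entries.append(
                ProteinEntry(
                    accession=f"SYN-{group.upper()[:4]}-{i + 1:02d}",
                    sequence=seq,
                    species=f"{group}_sp{i + 1:02d}",
                    group=group,
                    mollusc_class=mollusc_class,
                )
            )
    return SimulatedFamily(ancestor=ancestor, entries=tuple(entries), params=params)


def tile_epitopes(
    ancestor: str,
    lengths: Sequence[int] = (15,),
    step: int = 3,
    allergen: str = "TM",
) -> list[EpitopeRecord]:
    """Tile epitope windows over the ancestor, 1-based inclusive positions.

    For each length L, windows start at 1, 1+step, ... while they fit;
    the peptide is the ancestor substring, so every record satisfies the
    span/length invariant by construction.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    records = []
    for L in lengths:
        if L > len(ancestor):
            raise ValidationError(f"epitope length {L} exceeds ancestor length")
        for start in range(1, len(ancestor) - L + 2, step):
            records.append(
                EpitopeRecord(
                    epitope_id=f"t{L:02d}_{start:04d}",
                    allergen=allergen,
                    peptide=ancestor[start - 1 : start - 1 + L],
                    start=start,
                    end=start + L - 1,
                    source="simulated",
                )
            )
    return records


def epitope_block_membership(
    epitope: EpitopeRecord, blocks: Sequence[tuple[int, int]]
) -> str:
    """'inside' if the span lies fully within one block, 'outside' if it
    touches no block, else 'partial'."""
    if epitope.start is None:
        raise ValidationError(f"epitope {epitope.epitope_id!r} has no position")
    for s, e in blocks:
        if s <= epitope.start and epitope.end <= e:
            return "inside"
    for s, e in blocks:
        if epitope.start <= e and s <= epitope.end:
            return "partial"
    return "outside"


@dataclass(frozen=True)
class SyntheticTruth:
    """Independently computed ground truth for a simulated dataset."""

    #: (epitope_id, accession) -> minimum mismatch count, None = no window
    min_mismatch: dict[tuple[str, str], int | None]
    #: epitope_id -> group -> presentation percentage at max_mismatch
    group_percent: dict[str, dict[str, float]]
    #: epitope_id -> group -> conserved in at least one species of the group
    group_conserved: dict[str, dict[str, bool]]
    #: epitope_id -> 'inside' / 'outside' / 'partial' (empty when no blocks given)
    block_membership: dict[str, str]
    max_mismatch: int


def _oracle_scan(peptide: str, sequence: str) -> int | None:
    """Reference all-offsets Hamming minimum; character loops on purpose."""
    L = len(peptide)
    if len(sequence) < L:
        return None
    best = L
    for offset in range(len(sequence) - L + 1):
        mism = 0
        for k in range(L):
            c = sequence[offset + k]
            if c != peptide[k] or c == "X":
                mism += 1
                if mism >= best:
                    break
        if mism < best:
            best = mism
            if best == 0:
                return 0
    return best


def truth_oracle(
    proteins: Sequence[ProteinEntry],
    epitopes: Sequence[EpitopeRecord],
    max_mismatch: int = 2,
    blocks: Sequence[tuple[int, int]] = (),
) -> SyntheticTruth:
    """Brute-force ground truth, written independently of the conservancy module.

    Group percentages use the species denominator, collapsing isoforms
    of one species by their minimum mismatch; species with no window
    count as not conserved.
    """
    pair_min: dict[tuple[str, str], int | None] = {}
    for e in epitopes:
        for p in proteins:
            pair_min[(e.epitope_id, p.accession)] = _oracle_scan(e.peptide, p.sequence)
    group_percent: dict[str, dict[str, float]] = {}
    group_conserved: dict[str, dict[str, bool]] = {}
    species_group: dict[str, str] = {}
    species_accs: dict[str, list[str]] = {}
    for p in proteins:
        if p.group is None:
            raise ValidationError(f"protein {p.accession!r} has no group label")
        species_group[p.species] = p.group
        species_accs.setdefault(p.species, []).append(p.accession)
    for e in epitopes:
        per_group_total: dict[str, int] = {}
        per_group_hit: dict[str, int] = {}
        for sp, accs in species_accs.items():
            g = species_group[sp]
            per_group_total[g] = per_group_total.get(g, 0) + 1
            mins = [
                pair_min[(e.epitope_id, a)]
                for a in accs
                if pair_min[(e.epitope_id, a)] is not None
            ]
            if mins and min(mins) <= max_mismatch:
                per_group_hit[g] = per_group_hit.get(g, 0) + 1
        group_percent[e.epitope_id] = {
            g: 100.0 * per_group_hit.get(g, 0) / n for g, n in per_group_total.items()
        }
        group_conserved[e.epitope_id] = {
            g: per_group_hit.get(g, 0) > 0 for g in per_group_total
        }
    membership = (
        {e.epitope_id: epitope_block_membership(e, blocks) for e in epitopes}
        if blocks
        else {}
    )
    return SyntheticTruth(
        min_mismatch=pair_min,
        group_percent=group_percent,
        group_conserved=group_conserved,
        block_membership=membership,
        max_mismatch=max_mismatch,
    )


def truth_to_rows(truth: SyntheticTruth) -> list[dict]:
    """Rows for a truth TSV (epitope_id, accession, min_mismatches)."""
    return [
        {
            "epitope_id": eid,
            "accession": acc,
            "min_mismatches": "NA" if v is None else v,
        }
        for (eid, acc), v in sorted(truth.min_mismatch.items())
    ]
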