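"""Group-level cross-reactivity analytics over conservancy matrices.

Builds per-group presentation percentages (fraction of species in a
taxonomic group carrying a conserved variant of each epitope), per-species
conserved-epitope fractions, the omnibus one-way ANOVA between groups,
Manhattan-distance hierarchical clustering of the mismatch heatmap, the
Venn partition that identifies pan-epitopes, merged cross-reactive
regions on the source allergen, mollusc-class reactivity patterns, and a
consistency checker for positioned epitope tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from epiconserve.conservancy import ConservationMatrix, DEFAULT_MAX_MISMATCH
from epiconserve.io_core import (
    EpitopeRecord,
    GroupConfig,
    MOLLUSC_CLASSES,
    ValidationError,
)

#: mollusc-class reactivity patterns a merged region can show
REGION_PATTERNS = (
    "all_mollusc",
    "cephalopod_gastropod",
    "bivalve_cephalopod",
    "crustacean_only",
    "other",
)


@dataclass
class GroupPresentation:
    """Per-epitope, per-group presentation percentages.

    ``percent`` has epitope ids as index and group labels as columns;
    a cell is 100 x (conserved species) / (group size) at the mismatch
    tolerance used to build it.
    """

    percent: pd.DataFrame
    group_sizes: dict[str, int]
    max_mismatch: int = DEFAULT_MAX_MISMATCH

    def to_tsv(self, path) -> None:
        out = self.percent.copy()
        out.index.name = "epitope_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class PanEpitopePartition:
    """Assignment of each epitope to one cell of the group-overlap Venn diagram."""

    #: epitope id -> frozenset of groups in which it is conserved
    groups_conserved: dict[str, frozenset[str]]
    #: the group universe the partition was computed over
    groups: tuple[str, ...]

    @property
    def cells(self) -> dict[frozenset[str], tuple[str, ...]]:
        out: dict[frozenset[str], list[str]] = {}
        for eid, gs in self.groups_conserved.items():
            out.setdefault(gs, []).append(eid)
        return {k: tuple(v) for k, v in out.items()}

    @property
    def pan_epitopes(self) -> tuple[str, ...]:
        universe = frozenset(self.groups)
        return tuple(
            eid for eid, gs in self.groups_conserved.items() if gs == universe
        )

    @property
    def cell_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.cells.items()}


@dataclass(frozen=True)
class Region:
    """A maximal run of mutually overlapping epitopes on the source allergen."""

    start: int
    end: int
    epitope_ids: tuple[str, ...]
    pattern: str | None = None

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA omnibus result."""

    f: float
    df_between: int
    df_within: int
    p_value: float

    def __post_init__(self) -> None:
        if self.f < 0 or self.df_between < 1 or self.df_within < 1:
            raise ValidationError("invalid ANOVA result")


@dataclass(frozen=True)
class PositionConflict:
    """Two positioned epitopes disagreeing about a residue they both cover."""

    position: int
    epitope_a: str
    epitope_b: str
    letter_a: str
    letter_b: str


@dataclass
class HeatmapClustering:
    """Row/column orderings and dendrograms from hierarchical clustering."""

    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


# ---------------------------------------------------------------------------
# Presentation and per-species fractions

def _species_min_mismatch(
    matrix: ConservationMatrix, config: GroupConfig
) -> pd.DataFrame:
    """Collapse isoform columns to species by taking the minimum mismatch.

    A species with no window in any isoform keeps the NaN sentinel.
    """
    species = [config.species(a) for a in matrix.accessions]
    unknown = []
    for sp in species:
        try:
            config.group_of(sp)
        except KeyError:
            unknown.append(sp)
    if unknown:
        raise ValidationError(
            f"accessions map to species with no group assignment: {sorted(set(unknown))}"
        )
    collapsed = matrix.data.T.groupby(pd.Index(species, name="species")).min().T
    return collapsed


def group_presentation(
    matrix: ConservationMatrix,
    config: GroupConfig,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    per_sequence: bool = False,
) -> GroupPresentation:
    """Percentage of each group's species in which each epitope is conserved.

    Isoforms of one species are collapsed by taking the minimum mismatch
    across them (denominator = species); pass ``per_sequence=True`` to
    keep every sequence as its own unit. Species with no window count as
    not conserved.
    """
    if per_sequence:
        collapsed = matrix.data.copy()
        unit_of = {a: a for a in matrix.accessions}
        members = {
            g: [a for a in matrix.accessions if config.species(a) in sps]
            for g, sps in config.groups.items()
        }
    else:
        collapsed = _species_min_mismatch(matrix, config)
        members = {
            g: [sp for sp in sps if sp in collapsed.columns]
            for g, sps in config.groups.items()
        }
    sizes = {g: len(m) for g, m in members.items()}
    empty = [g for g, n in sizes.items() if n == 0]
    if empty:
        raise ValidationError(f"groups with no sequences in the matrix: {empty}")
    conserved = collapsed.le(max_mismatch)  # NaN (no window) -> False
    percent = pd.DataFrame(
        {g: 100.0 * conserved[m].sum(axis=1) / sizes[g] for g, m in members.items()},
        index=matrix.epitope_ids,
    )
    return GroupPresentation(percent=percent, group_sizes=sizes, max_mismatch=max_mismatch)


def mollusc_class_presentation(
    matrix: ConservationMatrix,
    config: GroupConfig,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> pd.DataFrame:
    """Presentation percentages within each mollusc class (bivalve, cephalopod, gastropod)."""
    if not config.mollusc_classes:
        raise ValidationError("GroupConfig has no mollusc classes")
    collapsed = _species_min_mismatch(matrix, config)
    conserved = collapsed.le(max_mismatch)
    cols = {}
    for cls in MOLLUSC_CLASSES:
        members = [
            sp for sp in config.mollusc_classes.get(cls, []) if sp in collapsed.columns
        ]
        if not members:
            raise ValidationError(f"mollusc class {cls!r} has no sequences in the matrix")
        cols[cls] = 100.0 * conserved[members].sum(axis=1) / len(members)
    return pd.DataFrame(cols, index=matrix.epitope_ids)


def conserved_fraction_per_species(
    matrix: ConservationMatrix,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    config: GroupConfig | None = None,
) -> pd.Series:
    """Per species (or per accession without a config), the fraction of epitopes conserved."""
    if matrix.data.empty:
        raise ValidationError("empty conservation matrix")
    data = _species_min_mismatch(matrix, config) if config is not None else matrix.data
    return data.le(max_mismatch).mean(axis=0)


# ---------------------------------------------------------------------------
# ANOVA

def one_way_anova(
    samples: Mapping[str, Sequence[float]],
    arcsine: bool = False,
) -> AnovaResult:
    """Classical one-way ANOVA across groups of per-species fractions.

    ``arcsine=True`` applies the arcsine-square-root variance-stabilising
    transform (inputs then must lie in [0, 1]); untransformed is the
    default.
    """
    if len(samples) < 2:
        raise ValidationError("one_way_anova: need at least 2 groups")
    groups = []
    for label, values in samples.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {label!r}: need at least 2 observations")
        if arcsine:
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError("arcsine transform requires values in [0, 1]")
            arr = np.arcsin(np.sqrt(arr))
        groups.append(arr)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        raise ValidationError(
            "one_way_anova: zero within-group variance in every group; F undefined"
        )
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return AnovaResult(f=float(f), df_between=k - 1, df_within=n - k, p_value=float(p))


# ---------------------------------------------------------------------------
# Heatmap clustering

def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def _cluster_axis(values: np.ndarray, labels: list[str], metric: str, method: str):
    if len(labels) < 2:
        return list(labels), f"{labels[0]};" if labels else ";", None
    linkage = hierarchy.linkage(pdist(values, metric=metric), method=method)
    order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    return order, _linkage_to_newick(linkage, labels), linkage


def cluster_heatmap(
    matrix: ConservationMatrix,
    metric: str = "cityblock",
    method: str = "average",
) -> HeatmapClustering:
    """Agglomerative clustering of heatmap rows and columns.

    Default is Manhattan (cityblock) distance with average linkage.
    No-window sentinels are imputed as L+1 for the epitope's length L —
    one worse than the worst possible real mismatch count — before
    distances are computed. Single row or column yields the identity
    ordering.
    """
    values = matrix.data.copy()
    for eid in values.index:
        L = matrix.epitope_lengths.get(eid)
        if values.loc[eid].isna().any():
            if L is None:
                raise ValidationError(
                    f"cannot impute sentinel for epitope {eid!r}: length unknown"
                )
            values.loc[eid] = values.loc[eid].fillna(L + 1)
    arr = values.to_numpy(dtype=float)
    row_order, row_newick, row_linkage = _cluster_axis(
        arr, list(values.index), metric, method
    )
    col_order, col_newick, col_linkage = _cluster_axis(
        arr.T, list(values.columns), metric, method
    )
    return HeatmapClustering(
        row_order=row_order,
        col_order=col_order,
        row_newick=row_newick,
        col_newick=col_newick,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )


# ---------------------------------------------------------------------------
# Venn partition / pan-epitopes

def venn_partition(
    presentation: GroupPresentation | pd.DataFrame,
    threshold: float = 0.0,
) -> PanEpitopePartition:
    """Assign each epitope to the Venn cell of groups where it is conserved.

    An epitope counts as conserved in a group when its presentation
    percentage exceeds ``threshold`` (default: any nonzero species
    suffices). Pan-epitopes are the cell conserved in every group.
    """
    percent = (
        presentation.percent
        if isinstance(presentation, GroupPresentation)
        else presentation
    )
    groups = tuple(percent.columns)
    assigned = {
        str(eid): frozenset(g for g in groups if percent.at[eid, g] > threshold)
        for eid in percent.index
    }
    return PanEpitopePartition(groups_conserved=assigned, groups=groups)


# ---------------------------------------------------------------------------
# Regions

def merge_epitope_regions(epitopes: Sequence[EpitopeRecord]) -> list[Region]:
    """Union of the epitopes' spans into maximal overlapping regions.

    Intervals are 1-based inclusive; only genuinely overlapping
    intervals merge — adjacent-but-disjoint spans stay separate regions.
    Output is in ascending, non-overlapping order.
    """
    unpositioned = [e.epitope_id for e in epitopes if e.start is None]
    if unpositioned:
        raise ValidationError(f"epitopes without positions: {unpositioned}")
    ordered = sorted(epitopes, key=lambda e: (e.start, e.end, e.epitope_id))
    regions: list[Region] = []
    for e in ordered:
        if regions and e.start <= regions[-1].end:
            last = regions[-1]
            regions[-1] = replace(
                last,
                end=max(last.end, e.end),
                epitope_ids=last.epitope_ids + (e.epitope_id,),
            )
        else:
            regions.append(Region(start=e.start, end=e.end, epitope_ids=(e.epitope_id,)))
    return regions


def total_region_residues(regions: Sequence[Region]) -> int:
    return sum(len(r) for r in regions)


def classify_region_pattern(
    region: Region,
    class_presentation: Mapping[str, float],
    threshold: float = 50.0,
) -> str:
    """Mollusc-class reactivity pattern of a region.

    ``class_presentation`` maps each mollusc class to the region's
    presentation percentage in that class. Classes above ``threshold``
    determine the label: all three -> ``all_mollusc``; cephalopod and
    gastropod only -> ``cephalopod_gastropod``; bivalve and cephalopod
    only -> ``bivalve_cephalopod``; none -> ``crustacean_only``; any
    other combination -> ``other``.
    """
    missing = [c for c in MOLLUSC_CLASSES if c not in class_presentation]
    if missing:
        raise ValidationError(
            f"region {region.start}-{region.end}: missing mollusc classes {missing}"
        )
    above = frozenset(c for c in MOLLUSC_CLASSES if class_presentation[c] > threshold)
    if above == frozenset(MOLLUSC_CLASSES):
        return "all_mollusc"
    if above == frozenset({"cephalopod", "gastropod"}):
        return "cephalopod_gastropod"
    if above == frozenset({"bivalve", "cephalopod"}):
        return "bivalve_cephalopod"
    if not above:
        return "crustacean_only"
    return "other"


def classify_regions(
    regions: Sequence[Region],
    class_percent: pd.DataFrame,
    threshold: float = 50.0,
) -> list[Region]:
    """Attach a mollusc-class pattern to each region.

    A region's per-class percentage is the maximum over its member
    epitopes (a class reacts with the region if any member epitope is
    conserved there).
    """
    out = []
    for r in regions:
        per_class = {
            c: float(class_percent.loc[list(r.epitope_ids), c].max())
            for c in MOLLUSC_CLASSES
        }
        out.append(replace(r, pattern=classify_region_pattern(r, per_class, threshold)))
    return out


# ---------------------------------------------------------------------------
# Fixture / table consistency

def consistency_check(records: Sequence[EpitopeRecord]) -> list[PositionConflict]:
    """Cross-validate the printed spans of positioned epitopes from one allergen.

    Every pair of overlapping spans is compared residue-by-residue at
    the positions both cover; each disagreement is reported, never
    corrected.
    """
    positioned = [r for r in records if r.start is not None]
    allergens = {r.allergen for r in positioned}
    if len(allergens) > 1:
        raise ValidationError(
            f"consistency_check expects records from one allergen, got {sorted(allergens)}"
        )
    conflicts = []
    for i, a in enumerate(positioned):
        for b in positioned[i + 1 :]:
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            for pos in range(lo, hi + 1):
                la = a.peptide[pos - a.start]
                lb = b.peptide[pos - b.start]
                if la != lb:
                    conflicts.append(
                        PositionConflict(
                            position=pos,
                            epitope_a=a.epitope_id,
                            epitope_b=b.epitope_id,
                            letter_a=la,
                            letter_b=lb,
                        )
                    )
    return conflicts
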