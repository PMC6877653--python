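"""Executable decision tree for molecular cross-reactivity diagnosis.

Maps a patient's serology (specific IgE to whole extract, tropomyosin
and arginine kinase) plus epitope-region reactivity to one of six
cross-reactivity classes. The tree has two serology branches:

* TM-positive (sIgE above the positivity cutoff and similar in
  magnitude to the whole-extract sIgE): the patient's reactive regions
  are checked against their mollusc-class conservation patterns in
  priority order all_mollusc > cephalopod_gastropod >
  bivalve_cephalopod, so that the broadest predicted avoidance
  dominates; no reactive cross-reactive region means crustacean
  mono-reactivity.
* TM-negative but AK-positive: reactivity to the designated AK region
  (the only AK region conserved in cephalopods) predicts
  crustacean-cephalopod cross-reactivity, otherwise crustacean
  mono-reactivity.

Neither positive yields ``none_detected``. This is a research tool for
reasoning about epitope conservation patterns, not a clinical device.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from epiconserve.io_core import ValidationError

CALL_CLASSES = (
    "crustacean_mono",
    "crustacean_mollusc",
    "crustacean_cephalopod_gastropod",
    "crustacean_cephalopod_bivalve",
    "crustacean_cephalopod_AK",
    "none_detected",
)

#: region pattern -> call it triggers on the TM branch, in priority order
_TM_PATTERN_CALLS = {
    "all_mollusc": "crustacean_mollusc",
    "cephalopod_gastropod": "crustacean_cephalopod_gastropod",
    "bivalve_cephalopod": "crustacean_cephalopod_bivalve",
}


@dataclass(frozen=True)
class PatientProfile:
    """Serology levels (arbitrary units, >= 0) plus per-region reactivity flags."""

    extract_sige: float
    tm_sige: float
    ak_sige: float
    region_reactivity: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.extract_sige, self.tm_sige, self.ak_sige) < 0:
            raise ValidationError("sIgE levels must be non-negative")


@dataclass
class DecisionConfig:
    """Region patterns and thresholds driving the decision tree.

    ``region_patterns`` maps TM region ids to their mollusc-class
    pattern label; ``ak_region`` names the AK region whose conservation
    in cephalopods carries the AK branch. ``positivity_cutoff`` is the
    conventional clinical sIgE threshold; ``tm_extract_ratio`` encodes
    "TM sIgE similar to whole-extract sIgE" as tm/extract >= ratio.
    """

    region_patterns: dict[str, str]
    ak_region: str | None = None
    positivity_cutoff: float = 0.35
    tm_extract_ratio: float = 0.7
    priority: tuple[str, ...] = (
        "all_mollusc",
        "cephalopod_gastropod",
        "bivalve_cephalopod",
    )

    def __post_init__(self) -> None:
        for rid, pattern in self.region_patterns.items():
            if pattern not in _TM_PATTERN_CALLS and pattern not in (
                "crustacean_only",
                "other",
            ):
                raise ValidationError(f"region {rid!r}: unknown pattern {pattern!r}")
        if set(self.priority) != set(_TM_PATTERN_CALLS):
            raise ValidationError(
                "priority must order exactly the three cross-reactive patterns"
            )

    @property
    def region_ids(self) -> tuple[str, ...]:
        ids = list(self.region_patterns)
        if self.ak_region is not None and self.ak_region not in ids:
            ids.append(self.ak_region)
        return tuple(ids)


def default_config() -> DecisionConfig:
    """A generic configuration with one region per mollusc-class pattern.

    Region definitions on real data should instead be computed from a
    conservancy run (``merge_epitope_regions`` + ``classify_regions``)
    and passed to :func:`config_from_regions`.
    """
    return DecisionConfig(
        region_patterns={
            "TM-R1": "all_mollusc",
            "TM-R2": "cephalopod_gastropod",
            "TM-R3": "bivalve_cephalopod",
            "TM-R4": "crustacean_only",
        },
        ak_region="AK-R1",
    )


def config_from_regions(tm_regions, ak_region_id: str | None = None, **kwargs) -> DecisionConfig:
    """Build a config from classified :class:`~epiconserve.crossreactivity.Region` objects."""
    patterns = {}
    for i, r in enumerate(tm_regions, start=1):
        if r.pattern is None:
            raise ValidationError(f"region {r.start}-{r.end} has no pattern label")
        patterns[f"TM-R{i}"] = r.pattern
    return DecisionConfig(region_patterns=patterns, ak_region=ak_region_id, **kwargs)


@dataclass(frozen=True)
class CrossReactivityCall:
    """One decision-tree outcome with the ordered node rationale."""

    call: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.call not in CALL_CLASSES:
            raise ValidationError(f"unknown call class {self.call!r}")


def decide(profile: PatientProfile, config: DecisionConfig) -> CrossReactivityCall:
    """Run one patient profile through the decision tree.

    Total and deterministic: every valid profile yields exactly one
    class. TM positivity requires both the positivity cutoff and sIgE
    similar to the whole-extract level (ratio test); a TM-positive but
    non-dominant profile falls through to the AK branch.
    """
    unknown = set(profile.region_reactivity) - set(config.region_ids)
    if unknown:
        raise ValidationError(f"profile references unknown regions: {sorted(unknown)}")
    rationale = []
    tm_pos = profile.tm_sige >= config.positivity_cutoff
    tm_dominant = tm_pos and (
        profile.extract_sige == 0
        or profile.tm_sige / profile.extract_sige >= config.tm_extract_ratio
    )
    ak_pos = profile.ak_sige >= config.positivity_cutoff
    if tm_dominant:
        rationale.append("TM sIgE positive and similar to whole-extract sIgE")
        for pattern in config.priority:
            hits = [
                rid
                for rid, p in config.region_patterns.items()
                if p == pattern and profile.region_reactivity.get(rid, False)
            ]
            if hits:
                rationale.append(f"reactive to {pattern} region(s): {', '.join(hits)}")
                return CrossReactivityCall(_TM_PATTERN_CALLS[pattern], tuple(rationale))
        rationale.append("no reactivity to mollusc-conserved TM regions")
        return CrossReactivityCall("crustacean_mono", tuple(rationale))
    if ak_pos:
        rationale.append("TM sIgE negative or not extract-dominant; AK sIgE positive")
        if config.ak_region is not None and profile.region_reactivity.get(
            config.ak_region, False
        ):
            rationale.append(f"reactive to cephalopod-conserved AK region {config.ak_region}")
            return CrossReactivityCall("crustacean_cephalopod_AK", tuple(rationale))
        rationale.append("no reactivity to the cephalopod-conserved AK region")
        return CrossReactivityCall("crustacean_mono", tuple(rationale))
    return CrossReactivityCall("none_detected", ())


def enumerate_outcomes(
    config: DecisionConfig,
    tm_branch_only: bool = False,
    include_none: bool = False,
) -> frozenset[str]:
    """All call classes reachable over boolean region profiles x serology signs.

    ``tm_branch_only`` restricts serology to TM-positive profiles;
    ``include_none`` keeps the no-sensitization outcome.
    """
    region_ids = config.region_ids
    if len(region_ids) > 16:
        raise ValidationError("too many regions to enumerate exhaustively")
    if tm_branch_only:
        serologies = [(1.0, 1.0, 0.0), (1.0, 1.0, 1.0)]
    else:
        serologies = [
            (1.0, tm, ak) for tm, ak in itertools.product((0.0, 1.0), repeat=2)
        ]
    reached = set()
    for extract, tm, ak in serologies:
        for bits in itertools.product((False, True), repeat=len(region_ids)):
            profile = PatientProfile(
                extract_sige=extract,
                tm_sige=tm,
                ak_sige=ak,
                region_reactivity=dict(zip(region_ids, bits)),
            )
            reached.add(decide(profile, config).call)
    if not include_none:
        reached.discard("none_detected")
    return frozenset(reached)
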