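"""Histological scoring systems for IBD biopsies.

Two instruments are modelled:

* **GHAS** (Global Histology Activity Score, Crohn's disease) — the five
  subgrades analysed downstream: epithelial damage (``EPDAM``), neutrophils
  in the epithelium (``PolysEP``), neutrophils in the lamina propria
  (``PolysLP``), mononuclear cells in the lamina propria (``MonosLP``) and
  ulceration (``ULCER``), each graded 0..3.  GHAS is scored per anatomical
  compartment (ileum or colon).
* **Geboes** (ulcerative colitis) — grades ``G0`` (architectural change),
  ``G1`` (chronic inflammatory infiltrate), ``G2A`` (eosinophils), ``G2B``
  (neutrophils in the lamina propria), ``G3`` (neutrophils in the
  epithelium), ``G4`` (crypt destruction) and ``G5`` (erosion/ulceration).
  Published sublevels (e.g. 2B.0-2B.3) are encoded as integers 0..3 per
  grade so all grades share uniform arithmetic.  Geboes applies to
  colon/rectum only.

The module also provides the presence-of-pathology binarization used for
binary model evaluation, the simplified-Geboes merge of the highest (and
typically rarest) severity levels within each grade, and pluggable
histological-improvement predicates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Mapping

__all__ = [
    "System",
    "Compartment",
    "PathologyFeature",
    "ScoreSet",
    "BinaryPathology",
    "GHAS_SUBGRADES",
    "GEBOES_GRADES",
    "SEVERITY_MAX",
    "binarize",
    "simplify_geboes",
    "histological_improvement",
    "register_improvement_rule",
    "ScoringError",
]


class ScoringError(ValueError):
    """Raised for severities, features or systems outside the score model."""


class System(str, enum.Enum):
    GHAS = "GHAS"
    GEBOES = "Geboes"


class Compartment(str, enum.Enum):
    ILEUM = "ileum"
    COLON = "colon"


GHAS_SUBGRADES: tuple[str, ...] = ("EPDAM", "PolysEP", "PolysLP", "MonosLP", "ULCER")
GEBOES_GRADES: tuple[str, ...] = ("G0", "G1", "G2A", "G2B", "G3", "G4", "G5")

#: every modelled subgrade spans the integer range 0..SEVERITY_MAX
SEVERITY_MAX = 3


def subgrades_for(system: System) -> tuple[str, ...]:
    return GHAS_SUBGRADES if System(system) is System.GHAS else GEBOES_GRADES


class PathologyFeature(str, enum.Enum):
    """Binary presence-of-pathology features shared by both instruments."""

    EPITHELIUM_DAMAGE = "epithelium_damage"
    NEUTROPHILS_EPITHELIUM = "neutrophils_epithelium"
    NEUTROPHILS_LAMINA_PROPRIA = "neutrophils_lamina_propria"
    MONONUCLEAR_OR_CHRONIC_INFLAMMATION = "mononuclear_or_chronic_inflammation"


# feature -> subgrade whose severity > 0 defines "pathology present"
_BINARIZE_MAP: dict[System, dict[PathologyFeature, str]] = {
    System.GHAS: {
        PathologyFeature.EPITHELIUM_DAMAGE: "EPDAM",
        PathologyFeature.NEUTROPHILS_EPITHELIUM: "PolysEP",
        PathologyFeature.NEUTROPHILS_LAMINA_PROPRIA: "PolysLP",
        PathologyFeature.MONONUCLEAR_OR_CHRONIC_INFLAMMATION: "MonosLP",
    },
    System.GEBOES: {
        PathologyFeature.EPITHELIUM_DAMAGE: "G5",
        PathologyFeature.NEUTROPHILS_EPITHELIUM: "G3",
        PathologyFeature.NEUTROPHILS_LAMINA_PROPRIA: "G2B",
        PathologyFeature.MONONUCLEAR_OR_CHRONIC_INFLAMMATION: "G1",
    },
}


@dataclass(frozen=True)
class ScoreSet:
    """Per-biopsy subgrade severities under one scoring system.

    Parameters
    ----------
    system
        ``System.GHAS`` or ``System.GEBOES``.
    compartment
        Anatomical compartment.  GHAS requires one of ileum/colon; Geboes
        is restricted to the colon/rectum.
    severities
        Mapping subgrade name -> integer severity.  Missing subgrades
        default to 0; unknown names or out-of-range severities raise
        :class:`ScoringError`.
    """

    system: System
    compartment: Compartment
    severities: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        system = System(self.system)
        compartment = Compartment(self.compartment)
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "compartment", compartment)
        valid = subgrades_for(system)
        full: dict[str, int] = {}
        for name in valid:
            sev = int(self.severities.get(name, 0))
            if not 0 <= sev <= SEVERITY_MAX:
                raise ScoringError(
                    f"severity {sev} for subgrade {name!r} outside 0..{SEVERITY_MAX}"
                )
            full[name] = sev
        unknown = set(self.severities) - set(valid)
        if unknown:
            raise ScoringError(
                f"unknown subgrade(s) {sorted(unknown)} for system {system.value}"
            )
        if system is System.GEBOES and compartment is not Compartment.COLON:
            raise ScoringError("Geboes scoring applies to colon/rectum biopsies only")
        object.__setattr__(self, "severities", full)

    def __getitem__(self, subgrade: str) -> int:
        return self.severities[subgrade]


@dataclass(frozen=True)
class BinaryPathology:
    feature: PathologyFeature
    present: bool


def binarize(score: ScoreSet, feature: PathologyFeature | str) -> BinaryPathology:
    """Map a ScoreSet to presence/absence of one histological feature.

    Presence is defined as the mapped subgrade severity being greater than
    zero (GHAS: EPDAM/PolysEP/PolysLP/MonosLP; Geboes: G5/G3/G2B/G1 for the
    same four features respectively).
    """
    feature = PathologyFeature(feature)
    mapping = _BINARIZE_MAP[score.system]
    if feature not in mapping:
        raise ScoringError(
            f"feature {feature.value!r} undefined for system {score.system.value}"
        )
    subgrade = mapping[feature]
    return BinaryPathology(feature=feature, present=score[subgrade] > 0)


#: default simplified-Geboes merge: within every grade the two highest
#: severity levels collapse into one (3 -> 2); override per grade via
#: ``merge_map={"G2B": {0:0, 1:1, 2:2, 3:2}, ...}``.
DEFAULT_GEBOES_MERGE: dict[int, int] = {0: 0, 1: 1, 2: 2, 3: 2}


def simplify_geboes(
    score: ScoreSet,
    merge_map: Mapping[str, Mapping[int, int]] | None = None,
) -> ScoreSet:
    """Collapse the highest severity levels of each Geboes grade.

    The highest severity levels within a grade are typically the least
    represented in trial data; merging them (default: level 3 into level 2)
    yields the simplified scale used for full-scale model evaluation.  The
    merge map must be order-preserving and never increase a severity, which
    makes the operation idempotent.
    """
    if score.system is not System.GEBOES:
        raise ScoringError("simplify_geboes requires a Geboes ScoreSet")
    merged: dict[str, int] = {}
    for grade, sev in score.severities.items():
        gmap = dict(DEFAULT_GEBOES_MERGE)
        if merge_map and grade in merge_map:
            gmap.update({int(k): int(v) for k, v in merge_map[grade].items()})
        levels = sorted(gmap)
        mapped = [gmap[level] for level in levels]
        if any(b < a for a, b in zip(mapped, mapped[1:])):
            raise ScoringError(f"merge map for {grade!r} is not order-preserving")
        if any(gmap[level] > level for level in levels):
            raise ScoringError(f"merge map for {grade!r} increases a severity")
        merged[grade] = gmap[sev]
    return ScoreSet(system=score.system, compartment=score.compartment, severities=merged)


ImprovementRule = Callable[[ScoreSet, ScoreSet], bool]
_IMPROVEMENT_RULES: dict[str, ImprovementRule] = {}


def register_improvement_rule(name: str, rule: ImprovementRule) -> None:
    _IMPROVEMENT_RULES[name] = rule


def _neutrophil_resolution(baseline: ScoreSet, followup: ScoreSet) -> bool:
    # absence of neutrophils with no crypt destruction and no
    # erosion/ulceration at follow-up; baseline is not consulted
    del baseline
    return all(followup[g] == 0 for g in ("G2B", "G3", "G4", "G5"))


def _delta_ge_1(baseline: ScoreSet, followup: ScoreSet) -> bool:
    return any(
        followup[g] < baseline[g] for g in baseline.severities
    )


register_improvement_rule("neutrophil_resolution", _neutrophil_resolution)
register_improvement_rule("delta_ge_1", _delta_ge_1)


def histological_improvement(
    baseline: ScoreSet,
    followup: ScoreSet,
    rule: str = "neutrophil_resolution",
) -> bool:
    """Evaluate a named improvement predicate on a baseline/follow-up pair.

    The shipped default, ``neutrophil_resolution``, declares improvement
    when the follow-up biopsy shows no neutrophils in lamina propria or
    epithelium and no crypt destruction or erosion/ulceration (Geboes G2B,
    G3, G4 and G5 all zero).  Additional predicates can be registered with
    :func:`register_improvement_rule`.
    """
    if baseline.system is not followup.system:
        raise ScoringError("baseline and follow-up use different scoring systems")
    if baseline.compartment is not followup.compartment:
        raise ScoringError("baseline and follow-up are from different compartments")
    if rule not in _IMPROVEMENT_RULES:
        raise ScoringError(
            f"unknown improvement rule {rule!r}; known: {sorted(_IMPROVEMENT_RULES)}"
        )
    return bool(_IMPROVEMENT_RULES[rule](baseline, followup))
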