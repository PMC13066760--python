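"""Exact mixture model of plasma cfDNA as a weighted set of contributors.

Each contributor (mother, fetal clone, twin, abnormal clone) has a mass
weight -- its diploid-genome fraction of total cfDNA -- and a multiset of
chromosome copies at the target locus, tagged by haplotype origin
(M1, M2, P1, P2, Y).  A copy carries weight/2 of mass, so a trisomic clone
contributes 3 x weight/2 at the locus; this is what makes trisomy FF ratios
"approximately half" rather than exactly half.

Expected allele frequencies follow by linear mass balance, and every
expected signature and regression slope is derived from them exactly.  This
module is the brute-force oracle against which the estimators, the
simulator, and the dilution regression are all checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .panel import (
    Panel,
    SnpLocus,
    SnpType,
    Subtype,
    build_panel,
    classify_snp,
)
from .signature import (
    FFEstimate,
    FFSignature,
    t1_value,
    t2_second_frequency,
    t3_value,
    t4_value,
)

__all__ = [
    "ScenarioKind",
    "Contributor",
    "ContributorSet",
    "Scenario",
    "contributors_for_scenario",
    "expected_allele_freqs",
    "expected_locus_mass",
    "expected_signature",
    "expected_slopes",
    "ExpectedSlopes",
    "dilute_contributors",
    "ABNORMAL_KINDS",
    "MATERNAL_SIDE_KINDS",
]

HAPLOTYPE_TAGS = ("M1", "M2", "P1", "P2", "Y")


class ScenarioKind(str, Enum):
    NORMAL = "NORMAL"
    TRI_MAT_MEI1 = "TRI_MAT_MEI1"
    TRI_MAT_MEI2 = "TRI_MAT_MEI2"
    TRI_PAT_MEI1 = "TRI_PAT_MEI1"
    TRI_PAT_MEI2 = "TRI_PAT_MEI2"
    MONOSOMY_MAT = "MONOSOMY_MAT"
    MONOSOMY_PAT = "MONOSOMY_PAT"
    UPD_MAT_ISO = "UPD_MAT_ISO"
    UPD_MAT_HETERO = "UPD_MAT_HETERO"
    UPD_PAT_ISO = "UPD_PAT_ISO"
    UPD_PAT_HETERO = "UPD_PAT_HETERO"
    TWINS_DIZYGOTIC = "TWINS_DIZYGOTIC"
    MALE_FETUS_X = "MALE_FETUS_X"
    XXY = "XXY"


#: kinds that admit a mosaic fraction (abnormal clone vs matching normal clone)
ABNORMAL_KINDS = frozenset(
    {
        ScenarioKind.TRI_MAT_MEI1,
        ScenarioKind.TRI_MAT_MEI2,
        ScenarioKind.TRI_PAT_MEI1,
        ScenarioKind.TRI_PAT_MEI2,
        ScenarioKind.MONOSOMY_MAT,
        ScenarioKind.MONOSOMY_PAT,
        ScenarioKind.UPD_MAT_ISO,
        ScenarioKind.UPD_MAT_HETERO,
        ScenarioKind.UPD_PAT_ISO,
        ScenarioKind.UPD_PAT_HETERO,
    }
)

#: kinds whose diagnostic signal sits on the maternal (Type-4) side
MATERNAL_SIDE_KINDS = frozenset(
    {
        ScenarioKind.TRI_MAT_MEI1,
        ScenarioKind.TRI_MAT_MEI2,
        ScenarioKind.MONOSOMY_MAT,
        ScenarioKind.UPD_MAT_ISO,
        ScenarioKind.UPD_MAT_HETERO,
    }
)


@dataclass(frozen=True)
class Contributor:
    """One cfDNA contributor: mass weight + chromosome copies at the locus.

    ``copies`` tags refer to parental haplotypes; a ``Y`` tag contributes
    only at Y loci (and nothing at X/autosome-like loci), mirroring a male
    fetus's hemizygous X.
    """

    label: str
    weight: float
    copies: Tuple[str, ...]

    def __post_init__(self):
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"{self.label}: weight outside [0,1]")
        for tag in self.copies:
            if tag not in HAPLOTYPE_TAGS:
                raise ValueError(f"{self.label}: unknown haplotype tag {tag}")


ContributorSet = Tuple[Contributor, ...]


def _validate_contributors(contributors: Sequence[Contributor]) -> None:
    total = sum(c.weight for c in contributors)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"contributor weights sum to {total}, expected 1")


@dataclass(frozen=True)
class Scenario:
    """A fully specified plasma composition.

    ``transmitted_maternal``/``transmitted_paternal`` are the haplotypes the
    (normal) fetal clone carries; ``mosaic_fraction`` m is the abnormal
    clone's share of fetal cfDNA mass (m=1 means homogeneous); ``twin_split``
    is twin #1's share of fetal mass, with twin #2 haplotypes given
    separately.
    """

    kind: ScenarioKind
    fetal_fraction: float
    transmitted_maternal: str = "M1"
    transmitted_paternal: str = "P1"
    mosaic_fraction: float = 1.0
    twin_split: Optional[float] = None
    twin2_maternal: str = "M2"
    twin2_paternal: str = "P2"

    def __post_init__(self):
        if not (0.0 <= self.fetal_fraction <= 1.0):
            raise ValueError("fetal_fraction outside [0,1]")
        if self.transmitted_maternal not in ("M1", "M2"):
            raise ValueError("transmitted_maternal must be M1 or M2")
        if self.transmitted_paternal not in ("P1", "P2"):
            raise ValueError("transmitted_paternal must be P1 or P2")
        if self.kind is ScenarioKind.TWINS_DIZYGOTIC:
            if self.twin_split is None or not (0.0 < self.twin_split < 1.0):
                raise ValueError("twins require twin_split in (0,1)")
        elif self.twin_split is not None:
            raise ValueError(f"twin_split is only valid for twins, not {self.kind.value}")
        if self.kind in ABNORMAL_KINDS:
            if not (0.0 < self.mosaic_fraction <= 1.0):
                raise ValueError("mosaic_fraction outside (0,1]")
        elif self.mosaic_fraction != 1.0:
            raise ValueError(
                f"mosaic_fraction is only valid for aneuploidy/UPD kinds, not {self.kind.value}"
            )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "fetal_fraction": self.fetal_fraction,
            "transmitted_maternal": self.transmitted_maternal,
            "transmitted_paternal": self.transmitted_paternal,
            "mosaic_fraction": self.mosaic_fraction,
            "twin_split": self.twin_split,
            "twin2_maternal": self.twin2_maternal,
            "twin2_paternal": self.twin2_paternal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            kind=ScenarioKind(d["kind"]),
            fetal_fraction=d["fetal_fraction"],
            transmitted_maternal=d.get("transmitted_maternal", "M1"),
            transmitted_paternal=d.get("transmitted_paternal", "P1"),
            mosaic_fraction=d.get("mosaic_fraction", 1.0),
            twin_split=d.get("twin_split"),
            twin2_maternal=d.get("twin2_maternal", "M2"),
            twin2_paternal=d.get("twin2_paternal", "P2"),
        )


def _abnormal_copies(scenario: Scenario) -> Tuple[str, ...]:
    tm = scenario.transmitted_maternal
    tp = scenario.transmitted_paternal
    kind = scenario.kind
    if kind is ScenarioKind.TRI_MAT_MEI1:
        return ("M1", "M2", tp)
    if kind is ScenarioKind.TRI_MAT_MEI2:
        return (tm, tm, tp)
    if kind is ScenarioKind.TRI_PAT_MEI1:
        return (tm, "P1", "P2")
    if kind is ScenarioKind.TRI_PAT_MEI2:
        return (tm, tp, tp)
    if kind is ScenarioKind.MONOSOMY_MAT:
        return (tm,)
    if kind is ScenarioKind.MONOSOMY_PAT:
        return (tp,)
    if kind is ScenarioKind.UPD_MAT_ISO:
        return (tm, tm)
    if kind is ScenarioKind.UPD_MAT_HETERO:
        return ("M1", "M2")
    if kind is ScenarioKind.UPD_PAT_ISO:
        return (tp, tp)
    if kind is ScenarioKind.UPD_PAT_HETERO:
        return ("P1", "P2")
    raise ValueError(f"kind {kind} has no abnormal clone")


def contributors_for_scenario(scenario: Scenario) -> ContributorSet:
    """Mother + fetal clone(s) with mass weights for a scenario."""
    f = scenario.fetal_fraction
    tm = scenario.transmitted_maternal
    tp = scenario.transmitted_paternal
    mother = Contributor("mother", 1.0 - f, ("M1", "M2"))
    kind = scenario.kind

    fetal: List[Contributor] = []
    if kind is ScenarioKind.NORMAL:
        fetal.append(Contributor("fetus", f, (tm, tp)))
    elif kind is ScenarioKind.TWINS_DIZYGOTIC:
        s = scenario.twin_split
        fetal.append(Contributor("twin1", f * s, (tm, tp)))
        fetal.append(
            Contributor(
                "twin2",
                f * (1.0 - s),
                (scenario.twin2_maternal, scenario.twin2_paternal),
            )
        )
    elif kind is ScenarioKind.MALE_FETUS_X:
        fetal.append(Contributor("fetus", f, (tm, "Y")))
    elif kind is ScenarioKind.XXY:
        fetal.append(Contributor("fetus", f, (tm, tp, "Y")))
    elif kind in ABNORMAL_KINDS:
        m = scenario.mosaic_fraction
        fetal.append(
            Contributor("abnormal_clone", f * m, _abnormal_copies(scenario))
        )
        if m < 1.0:
            fetal.append(
                Contributor("normal_clone", f * (1.0 - m), (tm, tp))
            )
    else:  # pragma: no cover
        raise ValueError(f"unhandled kind {kind}")

    contributors = (mother, *[c for c in fetal if c.weight > 0.0])
    _validate_contributors(contributors)
    return contributors


def mother_only_contributors() -> ContributorSet:
    return (Contributor("mother", 1.0, ("M1", "M2")),)


def dilute_contributors(
    contributors: Sequence[Contributor], p: float
) -> ContributorSet:
    """Mix a contributor set with pure maternal material, proportion p sample."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p outside [0,1]")
    out = []
    for c in contributors:
        w = c.weight * p
        if c.label == "mother":
            w += 1.0 - p
        if w > 0:
            out.append(replace(c, weight=w))
    result = tuple(out)
    _validate_contributors(result)
    return result


def _tag_allele(tag: str, locus: SnpLocus) -> Optional[str]:
    if tag == "M1":
        return locus.maternal_hap[0]
    if tag == "M2":
        return locus.maternal_hap[1]
    if tag == "P1":
        return locus.paternal_hap[0]
    if tag == "P2":
        return locus.paternal_hap[1]
    return None  # Y copy carries no allele at an X/autosome-like locus


def expected_locus_mass(
    contributors: Sequence[Contributor], locus: SnpLocus
) -> float:
    """Total copy mass at the locus, relative to one diploid genome = 1."""
    total = 0.0
    for c in contributors:
        for tag in c.copies:
            if locus.is_y_locus:
                total += c.weight / 2.0 if tag == "Y" else 0.0
            elif tag != "Y":
                total += c.weight / 2.0
    return total


def expected_allele_freqs(
    contributors: Sequence[Contributor], locus: SnpLocus
) -> Dict[str, float]:
    """Exact expected allele frequencies at a locus by linear mass balance."""
    _validate_contributors(contributors)
    mass: Dict[str, float] = {}
    for c in contributors:
        for tag in c.copies:
            if locus.is_y_locus:
                if tag == "Y":
                    # Y loci are presence markers; book all mass on one allele
                    mass["A"] = mass.get("A", 0.0) + c.weight / 2.0
                continue
            allele = _tag_allele(tag, locus)
            if allele is not None:
                mass[allele] = mass.get(allele, 0.0) + c.weight / 2.0
    total = sum(mass.values())
    if total <= 0:
        raise ZeroDivisionError("zero total mass at locus")
    return {a: m / total for a, m in mass.items()}


# canonical one-locus-per-class mini panel used for exact signatures
def _reference_panel() -> Panel:
    loci = [
        SnpLocus("t1", "X", 100, ("A", "A"), ("G", "G")),
        SnpLocus("t2", "X", 200, ("A", "A"), ("A", "A")),
        SnpLocus("t3_p1", "X", 300, ("A", "A"), ("G", "A")),
        SnpLocus("t3_p2", "X", 400, ("A", "A"), ("A", "G")),
        SnpLocus("t4_alpha", "X", 500, ("A", "G"), ("A", "A")),
        SnpLocus("t4_beta", "X", 600, ("A", "G"), ("G", "G")),
        SnpLocus("t5", "X", 700, ("A", "G"), ("A", "G")),
        SnpLocus("y1", "Y", 800, is_y_locus=True),
    ]
    return build_panel(loci)


_REF_PANEL = _reference_panel()


def expected_signature(scenario: Scenario) -> FFSignature:
    """Noise-free signature: estimators applied to exact frequencies."""
    contributors = contributors_for_scenario(scenario)
    return signature_of_contributors(contributors)


def signature_of_contributors(
    contributors: Sequence[Contributor],
) -> FFSignature:
    panel = _REF_PANEL

    def exact(snp_id: str, fn) -> FFEstimate:
        locus = panel.get(snp_id)
        freqs = expected_allele_freqs(contributors, locus)
        value = fn(freqs, locus)
        return FFEstimate(
            value=value, dispersion=0.0, n_snps=1, per_snp=_one(value)
        )

    ff_t1 = exact("t1", t1_value)
    ff_t3 = {
        Subtype.T3_P1: exact("t3_p1", t3_value),
        Subtype.T3_P2: exact("t3_p2", t3_value),
    }
    ff_t4 = {
        Subtype.T4_ALPHA: exact("t4_alpha", t4_value),
        Subtype.T4_BETA: exact("t4_beta", t4_value),
    }
    background = exact("t2", lambda fr, loc: t2_second_frequency(fr))

    # Y side: compare Y-locus mass against the shared non-Y locus mass
    y_locus = panel.get("y1")
    y_mass = expected_locus_mass(contributors, y_locus)
    ref_mass = expected_locus_mass(contributors, panel.get("t1"))
    if y_mass > 0 and ref_mass > 0:
        val = 2.0 * y_mass / ref_mass
        ff_y = FFEstimate(value=val, dispersion=0.0, n_snps=1,
                          per_snp=_one(val))
        sex_call = "male"
    else:
        ff_y, sex_call = None, "female"

    xxy = sex_call == "male" and any(
        est.value > 1e-12 for est in ff_t3.values()
    )

    return FFSignature(
        ff_t1=ff_t1,
        ff_t3=ff_t3,
        ff_t4=ff_t4,
        background=background,
        background_ff=background.doubled(),
        ff_y=ff_y,
        sex_call=sex_call,
        xxy_flag=xxy,
        class_counts=panel.counts_by_class,
    )


def _one(value: float) -> np.ndarray:
    return np.asarray([value], dtype=float)


@dataclass(frozen=True)
class ExpectedSlopes:
    """Exact Type-4-vs-Type-1 regression slopes (undefined if no T1 signal)."""

    alpha: Optional[float]
    beta: Optional[float]
    defined: bool
    note: str = ""


def expected_slopes(scenario: Scenario) -> ExpectedSlopes:
    """Exact dilution-regression slopes.

    Every non-Y locus shares the same total mass under a scenario, so the
    Type-4 : Type-1 ratio is invariant under in-silico dilution and the
    regression is linear through the origin; the slope is just the ratio of
    expected values.
    """
    sig = expected_signature(scenario)
    t1 = sig.ff_t1.value
    if abs(t1) < 1e-12:
        return ExpectedSlopes(
            alpha=None,
            beta=None,
            defined=False,
            note="no Type-1 signal; slopes undefined",
        )
    return ExpectedSlopes(
        alpha=sig.ff_t4[Subtype.T4_ALPHA].value / t1,
        beta=sig.ff_t4[Subtype.T4_BETA].value / t1,
        defined=True,
    )
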