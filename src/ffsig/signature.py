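"""Fetal-fraction signature computation from per-SNP allele counts.

Estimators (all on the fraction scale, percents only at the report layer):

* Type-1: FF = 2 x frequency of the paternal allele, averaged over loci.
* Type-3 (per subtype): FF = 2 x frequency of the paternal-specific allele;
  only the subtype on the transmitted haplotype carries signal in a normal
  pregnancy, the other falls within sequencing noise.
* Type-2 background: mean second-most-frequent allele frequency; also
  reported doubled so it is comparable with the Type-1/3 scale.
* Type-4 (per subtype, signed): mean of freq(M1 allele) - freq(M2 allele);
  positive means M1 over-represented.
* Y loci: fetal sex call and, for a male fetus, FF = 2 x (mean Y depth /
  reference depth), since the fetus carries one Y copy against two copies
  per genome elsewhere.

Dispersion is the mean absolute deviation of per-SNP values around their
mean ("average deviation" error bars); the sample standard deviation is kept
alongside for the alert rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .panel import Panel, SnpLocus, SnpType, Subtype

logger = logging.getLogger(__name__)

ALLELES: Tuple[str, ...] = ("A", "C", "G", "T")
ALLELE_INDEX: Dict[str, int] = {a: i for i, a in enumerate(ALLELES)}

__all__ = [
    "ALLELES",
    "AlleleCountTable",
    "FFEstimate",
    "FFSignature",
    "allele_frequencies",
    "estimate_ff_type1",
    "estimate_ff_type3",
    "estimate_ff_type4",
    "estimate_background",
    "estimate_ff_y",
    "compute_signature",
    "t1_value",
    "t3_value",
    "t4_value",
    "t2_second_frequency",
]


class AlleleCountTable:
    """Per-SNP, per-allele consensus-read counts for one sample.

    Counts are stored as a float array in A,C,G,T order (floats so exact
    in-silico dilution can bypass integer rounding); negative or non-finite
    counts are rejected.
    """

    def __init__(self, counts: Mapping[str, Sequence[float]]):
        self._counts: Dict[str, np.ndarray] = {}
        for snp_id, row in counts.items():
            arr = np.asarray(row, dtype=float)
            if arr.shape != (4,):
                raise ValueError(f"{snp_id}: expected 4 allele counts")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{snp_id}: counts must be finite and >= 0")
            self._counts[snp_id] = arr

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._counts

    @property
    def snp_ids(self) -> Tuple[str, ...]:
        return tuple(self._counts)

    def counts(self, snp_id: str) -> np.ndarray:
        return self._counts[snp_id]

    def depth(self, snp_id: str) -> float:
        return float(self._counts[snp_id].sum())

    def frequencies(self, snp_id: str) -> np.ndarray:
        d = self.depth(snp_id)
        if d <= 0:
            raise ZeroDivisionError(f"{snp_id}: zero depth")
        return self._counts[snp_id] / d

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._counts.items()}

    def scaled(self, factor: float) -> "AlleleCountTable":
        return AlleleCountTable(
            {k: v * factor for k, v in self._counts.items()}
        )


def allele_frequencies(counts: Mapping[str, float]) -> Dict[str, float]:
    """Normalise one SNP's allele counts to frequencies (sum 1)."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ZeroDivisionError("zero depth")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative count")
    return {a: c / total for a, c in counts.items()}


# ---------------------------------------------------------------------------
# per-SNP frequency-level estimators, shared with the exact mixture oracle
# ---------------------------------------------------------------------------

def t1_value(freqs: Mapping[str, float], locus: SnpLocus) -> float:
    """FF from one Type-1 SNP: twice the paternal-allele frequency."""
    return 2.0 * freqs.get(locus.paternal_hap[0], 0.0)


def t3_value(freqs: Mapping[str, float], locus: SnpLocus) -> float:
    """FF from one Type-3 SNP: twice the paternal-specific allele frequency."""
    cls = locus.classification
    return 2.0 * freqs.get(cls.paternal_specific_allele, 0.0)


def t4_value(freqs: Mapping[str, float], locus: SnpLocus) -> float:
    """Signed allelic-balance difference freq(M1 allele) - freq(M2 allele)."""
    cls = locus.classification
    return freqs.get(cls.m1_allele, 0.0) - freqs.get(cls.m2_allele, 0.0)


def t2_second_frequency(freqs: Mapping[str, float]) -> float:
    """Second-most-frequent allele frequency (background noise proxy)."""
    vals = sorted(freqs.values(), reverse=True)
    return vals[1] if len(vals) > 1 else 0.0


@dataclass
class FFEstimate:
    """One FF estimate: mean over loci, with dispersion and per-SNP values."""

    value: float
    dispersion: float
    n_snps: int
    per_snp: np.ndarray = field(default_factory=lambda: np.empty(0))
    available: bool = True

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "FFEstimate":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return cls.unavailable()
        mean = float(arr.mean())
        mad = float(np.abs(arr - mean).mean())
        return cls(value=mean, dispersion=mad, n_snps=arr.size, per_snp=arr)

    @classmethod
    def unavailable(cls) -> "FFEstimate":
        return cls(
            value=math.nan, dispersion=math.nan, n_snps=0, available=False
        )

    @property
    def sd(self) -> float:
        """Sample standard deviation across SNPs (alert-rule metric)."""
        if self.n_snps >= 2:
            return float(np.std(self.per_snp, ddof=1))
        return 0.0

    def doubled(self) -> "FFEstimate":
        if not self.available:
            return FFEstimate.unavailable()
        return FFEstimate(
            value=2.0 * self.value,
            dispersion=2.0 * self.dispersion,
            n_snps=self.n_snps,
            per_snp=2.0 * self.per_snp,
            available=True,
        )

    def to_dict(self) -> dict:
        return {
            "value": self.value if self.available else None,
            "dispersion": self.dispersion if self.available else None,
            "sd": self.sd if self.available else None,
            "n_snps": self.n_snps,
            "available": self.available,
        }


@dataclass
class FFSignature:
    """The full bar-chart object: FF per SNP class plus background and Y."""

    ff_t1: FFEstimate
    ff_t3: Dict[Subtype, FFEstimate]
    ff_t4: Dict[Subtype, FFEstimate]
    background: FFEstimate
    background_ff: FFEstimate
    ff_y: Optional[FFEstimate] = None
    sex_call: Optional[str] = None
    xxy_flag: bool = False
    class_counts: Dict[str, int] = field(default_factory=dict)
    excluded: Dict[str, int] = field(default_factory=dict)
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "ff_t1": self.ff_t1.to_dict(),
            "ff_t3": {k.value: v.to_dict() for k, v in self.ff_t3.items()},
            "ff_t4": {k.value: v.to_dict() for k, v in self.ff_t4.items()},
            "background": self.background.to_dict(),
            "background_ff": self.background_ff.to_dict(),
            "ff_y": self.ff_y.to_dict() if self.ff_y is not None else None,
            "sex_call": self.sex_call,
            "xxy_flag": self.xxy_flag,
            "class_counts": self.class_counts,
            "excluded": self.excluded,
            "flags": list(self.flags),
        }


def _usable_loci(
    counts: AlleleCountTable,
    loci: Iterable[SnpLocus],
    max_unexpected_freq: float,
    excluded: Dict[str, int],
):
    """Yield (locus, freqs-dict) for loci passing depth/consistency checks."""
    for locus in loci:
        if locus.snp_id not in counts:
            excluded["missing"] = excluded.get("missing", 0) + 1
            continue
        arr = counts.counts(locus.snp_id)
        depth = arr.sum()
        if depth <= 0:
            excluded["zero_depth"] = excluded.get("zero_depth", 0) + 1
            continue
        freqs = arr / depth
        expected = locus.expected_alleles
        bad = any(
            freqs[i] > max_unexpected_freq
            for i, a in enumerate(ALLELES)
            if a not in expected
        )
        if bad:
            excluded["inconsistent"] = excluded.get("inconsistent", 0) + 1
            logger.warning(
                "%s: unexpected allele above %.2f, excluded",
                locus.snp_id,
                max_unexpected_freq,
            )
            continue
        yield locus, {a: float(freqs[i]) for i, a in enumerate(ALLELES)}


def _estimate(
    counts: AlleleCountTable,
    loci,
    per_snp_fn,
    max_unexpected_freq: float = 0.20,
    excluded: Optional[Dict[str, int]] = None,
) -> FFEstimate:
    excluded = {} if excluded is None else excluded
    values = [
        per_snp_fn(freqs, locus)
        for locus, freqs in _usable_loci(
            counts, loci, max_unexpected_freq, excluded
        )
    ]
    return FFEstimate.from_values(values)


def estimate_ff_type1(
    counts: AlleleCountTable, panel: Panel, **kw
) -> FFEstimate:
    return _estimate(counts, panel.loci_of_class(SnpType.T1), t1_value, **kw)


def estimate_ff_type3(
    counts: AlleleCountTable, panel: Panel, subtype: Subtype, **kw
) -> FFEstimate:
    if subtype not in (Subtype.T3_P1, Subtype.T3_P2):
        raise ValueError(f"not a Type-3 subtype: {subtype}")
    return _estimate(
        counts, panel.loci_of_class(SnpType.T3, subtype), t3_value, **kw
    )


def estimate_ff_type4(
    counts: AlleleCountTable, panel: Panel, subtype: Subtype, **kw
) -> FFEstimate:
    if subtype not in (Subtype.T4_ALPHA, Subtype.T4_BETA):
        raise ValueError(f"not a Type-4 subtype: {subtype}")
    return _estimate(
        counts, panel.loci_of_class(SnpType.T4, subtype), t4_value, **kw
    )


def estimate_background(
    counts: AlleleCountTable, panel: Panel, **kw
) -> FFEstimate:
    return _estimate(
        counts,
        panel.loci_of_class(SnpType.T2),
        lambda freqs, locus: t2_second_frequency(freqs),
        **kw,
    )


def estimate_ff_y(
    counts: AlleleCountTable,
    panel: Panel,
    reference_depth: Optional[float] = None,
    male_depth_ratio: float = 0.01,
) -> Tuple[Optional[FFEstimate], str]:
    """Fetal sex call and male-fetus FF from Y-locus depth.

    The fetus is called male when the mean Y depth exceeds
    ``male_depth_ratio`` times the reference depth (mean over non-Y loci by
    default).  For a male fetus FF_Y = 2 x (mean Y depth / reference depth).
    """
    y_loci = panel.y_loci
    if not y_loci:
        raise ValueError("panel has no Y loci")
    if reference_depth is None:
        depths = [
            counts.depth(l.snp_id)
            for l in panel.autosomal_like_loci
            if l.snp_id in counts
        ]
        if not depths:
            raise ValueError("no non-Y loci to set the reference depth")
        reference_depth = float(np.mean(depths))
    if reference_depth <= 0:
        raise ValueError("reference depth must be positive")
    y_depths = np.asarray(
        [counts.depth(l.snp_id) for l in y_loci if l.snp_id in counts],
        dtype=float,
    )
    if y_depths.size == 0:
        return None, "female"
    ratio = y_depths.mean() / reference_depth
    if ratio <= male_depth_ratio:
        return None, "female"
    per_snp = 2.0 * y_depths / reference_depth
    return FFEstimate.from_values(per_snp), "male"


def compute_signature(
    counts: AlleleCountTable,
    panel: Panel,
    max_unexpected_freq: float = 0.20,
    male_depth_ratio: float = 0.01,
    xxy_t3_factor: float = 5.0,
) -> FFSignature:
    """Assemble the full FF signature for one sample.

    Missing classes yield unavailable estimates with explicit flags rather
    than errors, so partial panels still produce a (partial) signature.
    """
    excluded: Dict[str, int] = {}
    kw = dict(max_unexpected_freq=max_unexpected_freq, excluded=excluded)

    ff_t1 = estimate_ff_type1(counts, panel, **kw)
    ff_t3 = {
        st: estimate_ff_type3(counts, panel, st, **kw)
        for st in (Subtype.T3_P1, Subtype.T3_P2)
    }
    ff_t4 = {
        st: estimate_ff_type4(counts, panel, st, **kw)
        for st in (Subtype.T4_ALPHA, Subtype.T4_BETA)
    }
    background = estimate_background(counts, panel, **kw)

    flags = []
    for name, est in (
        ("T1", ff_t1),
        ("T3_P1", ff_t3[Subtype.T3_P1]),
        ("T3_P2", ff_t3[Subtype.T3_P2]),
        ("T4_ALPHA", ff_t4[Subtype.T4_ALPHA]),
        ("T4_BETA", ff_t4[Subtype.T4_BETA]),
        ("background", background),
    ):
        if not est.available:
            flags.append(f"no usable {name} SNPs")

    ff_y = None
    sex_call = None
    if panel.y_loci:
        try:
            ff_y, sex_call = estimate_ff_y(
                counts, panel, male_depth_ratio=male_depth_ratio
            )
        except ValueError as exc:
            flags.append(str(exc))

    # male Y signal together with a clear paternal haplotype at Type-3 SNPs
    # suggests 47,XXY (a normal male X carries no paternal X haplotype)
    xxy = False
    if sex_call == "male" and background.available:
        threshold = max(
            0.01, xxy_t3_factor * 2.0 * (background.value + background.sd)
        )
        xxy = any(
            est.available and est.value > threshold for est in ff_t3.values()
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
        excluded=excluded,
        flags=tuple(flags),
    )
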