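"""QC calls from a fetal-fraction signature and optional regression result.

Three layers:

* an alert rule comparing each Type-3/Type-4 subtype interval (mean +/- 1 SD
  across SNPs) against two controls -- Type-1 (signal) and Type-2 background
  (null, on matching scale); a consistent normal pattern needs exactly one
  signal-conforming and one null-conforming subtype per parental side;
* a slope flag testing the dilution-regression slopes against the normal
  branches (+1, 0) and (0, -1);
* a scenario classifier fitting the exact mixture model over scenario kind,
  fetal fraction and mosaic fraction, reporting known indistinguishable
  scenario groups as tied sets rather than a unique call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .dilution import RegressionResult
from .oracle import (
    ABNORMAL_KINDS,
    Scenario,
    ScenarioKind,
    expected_signature,
    expected_slopes,
)
from .panel import Subtype
from .signature import FFEstimate, FFSignature

__all__ = [
    "AlertResult",
    "SlopeFlag",
    "ScenarioFit",
    "ClassificationResult",
    "AnomalyCall",
    "alert_from_signature",
    "slope_flags",
    "classify_scenario",
    "estimate_mosaic_fraction",
    "call_sample",
]

_T3_SUBTYPES = (Subtype.T3_P1, Subtype.T3_P2)
_T4_SUBTYPES = (Subtype.T4_ALPHA, Subtype.T4_BETA)

#: scenario groups that cannot be separated without off-chromosome SNPs.
#: Each yields identical allele-ratio signatures once the fetal fraction is
#: free: e.g. homogeneous maternal MI trisomy at FF f matches paternal
#: isodisomy at FF f/(1+f/2), and discordant twins match a mosaic paternal
#: heterodisomy.  Only the apparent-vs-true FF differs, which requires SNPs
#: on other chromosomes to measure.
INDISTINGUISHABLE_GROUPS: Tuple[Tuple[str, ...], ...] = (
    ("MONOSOMY_MAT", "UPD_MAT_ISO", "MALE_FETUS_X"),
    ("MONOSOMY_PAT", "UPD_PAT_ISO"),
    ("TRI_MAT_MEI1", "UPD_PAT_ISO"),
    ("TWINS_DIZYGOTIC", "UPD_PAT_HETERO"),
    ("UPD_MAT_HETERO", "NO_FETAL_DNA"),
)

#: tie-break order when fit distances are numerically indistinguishable:
#: the null hypothesis first, then primary aneuploidies, then UPDs
_KIND_PREFERENCE = {
    kind: i
    for i, kind in enumerate(
        (
            "NORMAL",
            "TRI_MAT_MEI1",
            "TRI_MAT_MEI2",
            "TRI_PAT_MEI1",
            "TRI_PAT_MEI2",
            "MONOSOMY_MAT",
            "MONOSOMY_PAT",
            "TWINS_DIZYGOTIC",
            "UPD_MAT_ISO",
            "UPD_PAT_ISO",
            "UPD_MAT_HETERO",
            "UPD_PAT_HETERO",
            "MALE_FETUS_X",
            "XXY",
        )
    )
}

_DISAMBIGUATION_NOTE = (
    "indistinguishable from signature alone; measuring FF with SNPs located "
    "on other chromosomes can resolve the ambiguity"
)


def _conformity(
    est: FFEstimate, sig: FFSignature
) -> Tuple[bool, bool]:
    """(conforms-to-signal, conforms-to-null) for one T3/T4 subtype.

    Overlap test on mean +/- 1 SD intervals: the subtype interval must reach
    within 1 SD of the control mean.  Signal control is Type-1 (compared on
    magnitude, since Type-4 is signed); null control is the doubled Type-2
    background (centred at zero for the signed Type-4 scale).
    """
    t1 = sig.ff_t1
    bkg = sig.background_ff
    if not (est.available and t1.available and bkg.available):
        return False, False
    is_signal = abs(abs(est.value) - t1.value) <= est.sd + t1.sd
    null_halfwidth = bkg.value + bkg.sd
    is_null = abs(est.value) <= est.sd + null_halfwidth
    return is_signal, is_null


@dataclass
class AlertResult:
    alert: bool
    reasons: Tuple[str, ...]
    low_confidence: bool
    conformity: Dict[Subtype, Tuple[bool, bool]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alert": self.alert,
            "reasons": list(self.reasons),
            "low_confidence": self.low_confidence,
            "conformity": {
                k.value: {"signal": s, "null": n}
                for k, (s, n) in self.conformity.items()
            },
        }


def alert_from_signature(
    sig: FFSignature, min_snps: int = 5
) -> AlertResult:
    """Tentative mean +/- 1 SD alert rule with dual controls."""
    reasons: List[str] = []
    low_confidence = False

    if not sig.ff_t1.available or not sig.background_ff.available:
        return AlertResult(
            alert=False,
            reasons=("controls unavailable",),
            low_confidence=True,
        )
    if sig.ff_t1.n_snps < min_snps or sig.background.n_snps < min_snps:
        return AlertResult(
            alert=False,
            reasons=(f"fewer than {min_snps} control SNPs",),
            low_confidence=True,
        )

    # no fetal signal at all: Type-1 indistinguishable from background
    t1, bkg = sig.ff_t1, sig.background_ff
    if abs(t1.value - bkg.value) <= t1.sd + bkg.sd:
        reasons.append(
            "Type-1 FF within background: no fetal DNA or maternal "
            "heterodisomy"
        )

    conformity: Dict[Subtype, Tuple[bool, bool]] = {}
    estimates = {**sig.ff_t3, **sig.ff_t4}
    usable: Dict[Subtype, Tuple[bool, bool]] = {}
    for subtype, est in estimates.items():
        if not est.available or est.n_snps < min_snps:
            low_confidence = True
            continue
        usable[subtype] = conformity[subtype] = _conformity(est, sig)

    for subtype, (is_signal, is_null) in usable.items():
        if not is_signal and not is_null:
            reasons.append(
                f"{subtype.value} conforms to neither the Type-1 nor the "
                "background control"
            )

    for side, pair in (("Type-3", _T3_SUBTYPES), ("Type-4", _T4_SUBTYPES)):
        if not all(st in usable for st in pair):
            continue
        (s1, n1), (s2, n2) = usable[pair[0]], usable[pair[1]]
        if not ((s1 and n2) or (s2 and n1)):
            reasons.append(
                f"{side} side lacks a one-signal/one-null normal pattern"
            )

    return AlertResult(
        alert=bool(reasons),
        reasons=tuple(reasons),
        low_confidence=low_confidence,
        conformity=conformity,
    )


@dataclass
class SlopeFlag:
    flagged: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {"flagged": self.flagged, "reason": self.reason}


def slope_flags(reg: RegressionResult, tolerance: float = 0.15) -> SlopeFlag:
    """Flag slopes not within tolerance of a normal branch (+1,0) or (0,-1)."""
    if not reg.defined or reg.slope_alpha is None:
        return SlopeFlag(
            flagged=True, reason=f"slopes undefined: {reg.note}"
        )
    sa, sb = reg.slope_alpha, reg.slope_beta
    for branch_a, branch_b in ((1.0, 0.0), (0.0, -1.0)):
        if abs(sa - branch_a) <= tolerance and abs(sb - branch_b) <= tolerance:
            return SlopeFlag(flagged=False)
    return SlopeFlag(
        flagged=True,
        reason=(
            f"slopes ({sa:.4f}, {sb:.4f}) outside tolerance {tolerance} of "
            "(+1, 0) and (0, -1)"
        ),
    )


# ---------------------------------------------------------------------------
# scenario classification
# ---------------------------------------------------------------------------

_VECTOR_KEYS = ("t1", "t3_p1", "t3_p2", "t4_alpha", "t4_beta")


def _sig_vector(sig: FFSignature) -> np.ndarray:
    vals = [
        sig.ff_t1.value if sig.ff_t1.available else math.nan,
        *(
            sig.ff_t3[st].value if sig.ff_t3[st].available else math.nan
            for st in _T3_SUBTYPES
        ),
        *(
            sig.ff_t4[st].value if sig.ff_t4[st].available else math.nan
            for st in _T4_SUBTYPES
        ),
    ]
    return np.asarray(vals, dtype=float)


def _sem(est: FFEstimate, floor: float) -> float:
    """Standard error of one class mean (floored so exact inputs stay finite)."""
    if not est.available:
        return math.inf
    if est.n_snps < 2:
        return floor
    return max(est.sd / math.sqrt(est.n_snps), floor)


def _sig_weights(sig: FFSignature, floor: float) -> np.ndarray:
    sems = [
        _sem(sig.ff_t1, floor),
        *(_sem(sig.ff_t3[st], floor) for st in _T3_SUBTYPES),
        *(_sem(sig.ff_t4[st], floor) for st in _T4_SUBTYPES),
    ]
    return np.asarray(
        [0.0 if not np.isfinite(s) else 1.0 / s**2 for s in sems]
    )


def _slope_sigma(sig: FFSignature, reg: RegressionResult) -> float:
    """Approximate noise SD of a fitted slope.

    The ladder points are deterministic mixes of the two measured tables, so
    the slope is endpoint-determined: sigma ~ sqrt(2) x SEM(Type-4) / span.
    """
    span = max(reg.ff_t1) - min(reg.ff_t1)
    sems = [
        _sem(sig.ff_t4[st], 1e-6)
        for st in _T4_SUBTYPES
        if sig.ff_t4[st].available
    ]
    if not sems or not np.isfinite(span) or span <= 0:
        return 0.05
    return max(math.sqrt(2.0) * float(np.mean(sems)) / span, 1e-3)


@dataclass
class ScenarioFit:
    kind: str
    fetal_fraction: float
    mosaic_fraction: Optional[float]
    transmitted_maternal: str
    transmitted_paternal: str
    twin_split: Optional[float]
    distance: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "fetal_fraction": self.fetal_fraction,
            "mosaic_fraction": self.mosaic_fraction,
            "transmitted_maternal": self.transmitted_maternal,
            "transmitted_paternal": self.transmitted_paternal,
            "twin_split": self.twin_split,
            "distance": self.distance,
        }


@dataclass
class ClassificationResult:
    fits: List[ScenarioFit]
    tied_kinds: Tuple[str, ...]
    notes: Tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "fits": [f.to_dict() for f in self.fits],
            "tied_kinds": list(self.tied_kinds),
            "notes": list(self.notes),
        }


def _distance(
    obs: np.ndarray,
    weights: np.ndarray,
    scenario: Scenario,
    obs_slopes: Optional[Tuple[float, float]],
    slope_weight: float,
) -> float:
    """Reduced chi-square of observed vs expected signature (+ slopes).

    ~1 when the candidate scenario explains the data within sampling noise.
    """
    exp_sig = expected_signature(scenario)
    exp = _sig_vector(exp_sig)
    mask = np.isfinite(obs) & (weights > 0)
    if not mask.any():
        return math.inf
    num = float(np.sum(weights[mask] * (obs[mask] - exp[mask]) ** 2))
    n_terms = int(mask.sum())
    if obs_slopes is not None:
        exp_sl = expected_slopes(scenario)
        if exp_sl.defined:
            res_a = obs_slopes[0] - exp_sl.alpha
            res_b = obs_slopes[1] - exp_sl.beta
        else:
            # observed slopes exist but the candidate predicts no Type-1
            # signal at all: charge a unit slope residual on both subtypes
            res_a = res_b = 1.0
        num += slope_weight * (res_a**2 + res_b**2)
        n_terms += 2
    return num / n_terms


def _fit_f(
    obs, weights, make_scenario, obs_slopes, slope_weight,
    f_bounds=(1e-4, 0.6),
):
    """Best fetal fraction (1-D bounded minimisation) for one candidate."""

    def loss(f: float) -> float:
        try:
            scen = make_scenario(f)
        except ValueError:
            return math.inf
        return _distance(obs, weights, scen, obs_slopes, slope_weight)

    res = minimize_scalar(
        loss, bounds=f_bounds, method="bounded",
        options={"xatol": 1e-5, "maxiter": 60},
    )
    return float(res.x), float(res.fun)


def _split_estimate(v1: float, v2: float) -> Optional[float]:
    a, b = abs(v1), abs(v2)
    if a + b <= 0:
        return None
    return min(max(a / (a + b), 0.02), 0.98)


def classify_scenario(
    sig: FFSignature,
    reg: Optional[RegressionResult] = None,
    mosaic_grid: Optional[Sequence[float]] = None,
    sem_floor: float = 1e-4,
    tie_rel_tol: float = 0.05,
    normal_chi2_cut: float = 3.0,
) -> ClassificationResult:
    """Grid/least-squares search over scenario kinds, ranked by fit distance."""
    obs = _sig_vector(sig)
    weights = _sig_weights(sig, sem_floor)
    obs_slopes = None
    slope_weight = 0.0
    if reg is not None and reg.defined and reg.slope_alpha is not None:
        obs_slopes = (reg.slope_alpha, reg.slope_beta)
        slope_weight = 1.0 / _slope_sigma(sig, reg) ** 2
    if mosaic_grid is None:
        mosaic_grid = np.round(np.arange(0.05, 1.0001, 0.05), 4)

    hap_combos = [
        (tm, tp) for tm in ("M1", "M2") for tp in ("P1", "P2")
    ]
    best_by_kind: Dict[str, ScenarioFit] = {}

    def consider(kind: ScenarioKind, make_scenario, tm, tp, m, split):
        f_hat, d = _fit_f(obs, weights, make_scenario, obs_slopes, slope_weight)
        fit = ScenarioFit(
            kind=kind.value,
            fetal_fraction=f_hat,
            mosaic_fraction=m,
            transmitted_maternal=tm,
            transmitted_paternal=tp,
            twin_split=split,
            distance=d,
        )
        prev = best_by_kind.get(kind.value)
        if prev is None or fit.distance < prev.distance:
            best_by_kind[kind.value] = fit

    for tm, tp in hap_combos:
        consider(
            ScenarioKind.NORMAL,
            lambda f, tm=tm, tp=tp: Scenario(
                ScenarioKind.NORMAL, f, tm, tp
            ),
            tm, tp, None, None,
        )

    for kind in sorted(ABNORMAL_KINDS, key=lambda k: k.value):
        # mosaic maternal heterodisomy is exactly a normal pregnancy with
        # reduced effective FF: only the homogeneous state is identifiable
        kind_grid = (
            (1.0,) if kind is ScenarioKind.UPD_MAT_HETERO else mosaic_grid
        )
        for tm, tp in hap_combos:
            for m in kind_grid:
                consider(
                    kind,
                    lambda f, kind=kind, tm=tm, tp=tp, m=m: Scenario(
                        kind, f, tm, tp, mosaic_fraction=float(m)
                    ),
                    tm, tp, float(m), None,
                )

    # dizygotic twins: haplotype pairs with a closed-form split estimate
    t3_obs = (obs[1], obs[2])
    t4_obs = (obs[3], obs[4])
    for i, (tm1, tp1) in enumerate(hap_combos):
        for tm2, tp2 in hap_combos[i + 1:]:
            if tp1 != tp2 and np.all(np.isfinite(t3_obs)):
                v1 = t3_obs[0] if tp1 == "P1" else t3_obs[1]
                v2 = t3_obs[0] if tp2 == "P1" else t3_obs[1]
                split = _split_estimate(v1, v2)
            elif tm1 != tm2 and np.all(np.isfinite(t4_obs)):
                va = abs(t4_obs[0]) if tm1 == "M1" else abs(t4_obs[1])
                vb = abs(t4_obs[0]) if tm2 == "M1" else abs(t4_obs[1])
                split = _split_estimate(va, vb)
            else:
                split = 0.5
            if split is None:
                continue
            consider(
                ScenarioKind.TWINS_DIZYGOTIC,
                lambda f, tm1=tm1, tp1=tp1, tm2=tm2, tp2=tp2, s=split: Scenario(
                    ScenarioKind.TWINS_DIZYGOTIC, f, tm1, tp1,
                    twin_split=s, twin2_maternal=tm2, twin2_paternal=tp2,
                ),
                tm1, tp1, None, split,
            )

    if sig.sex_call == "male":
        for tm, tp in hap_combos:
            consider(
                ScenarioKind.MALE_FETUS_X,
                lambda f, tm=tm: Scenario(ScenarioKind.MALE_FETUS_X, f, tm),
                tm, tp, None, None,
            )
            consider(
                ScenarioKind.XXY,
                lambda f, tm=tm, tp=tp: Scenario(ScenarioKind.XXY, f, tm, tp),
                tm, tp, None, None,
            )

    fits = sorted(best_by_kind.values(), key=lambda fit: fit.distance)
    if not fits or not math.isfinite(fits[0].distance):
        return ClassificationResult(
            fits=fits, tied_kinds=(), notes=("unclassifiable",)
        )

    # exact model degeneracies leave numerically tied fits whose distances
    # differ only by optimiser precision (reduced chi-square << 1 in every
    # case); break such ties by canonical preference, not float luck
    best = fits[0].distance
    head_cut = max(0.01, best * 1.02 + 1e-12)
    head = [f for f in fits if f.distance <= head_cut]
    tail = [f for f in fits if f.distance > head_cut]
    head.sort(key=lambda fit: _KIND_PREFERENCE.get(fit.kind, 99))
    fits = head + tail

    # several kinds contain a (near-)normal limit and can absorb noise via
    # their extra mosaic parameter; when NORMAL explains the data within
    # sampling noise (reduced chi-square ~1) or essentially as well as the
    # best fit, prefer the null hypothesis
    head_margin = max(normal_chi2_cut, fits[0].distance * 1.25 + 1e-9)
    for i, fit in enumerate(fits):
        if fit.kind == ScenarioKind.NORMAL.value:
            if fit.distance <= head_margin:
                fits.insert(0, fits.pop(i))
            break

    best = fits[0].distance
    tie_cut = max(0.01, best + tie_rel_tol * (best + 1e-9))
    tied = [f.kind for f in fits if f.distance <= tie_cut]

    notes: List[str] = []
    top = fits[0]
    homogeneous_top = top.mosaic_fraction in (None, 1.0)
    for group in INDISTINGUISHABLE_GROUPS:
        if top.kind in group and homogeneous_top:
            for member in group:
                if member == "MALE_FETUS_X" and sig.sex_call != "male":
                    continue
                if member not in tied:
                    tied.append(member)
            notes.append(
                f"{'/'.join(group)}: {_DISAMBIGUATION_NOTE}"
            )
    if top.kind == ScenarioKind.NORMAL.value:
        if top.fetal_fraction < 0.01:
            for member in ("UPD_MAT_HETERO", "NO_FETAL_DNA"):
                if member not in tied:
                    tied.append(member)
            notes.append(
                "no measurable fetal signal: "
                "UPD_MAT_HETERO/NO_FETAL_DNA: " + _DISAMBIGUATION_NOTE
            )
        else:
            notes.append(
                "fully concordant dizygotic twins are indistinguishable "
                "from a singleton at this locus"
            )

    return ClassificationResult(
        fits=fits, tied_kinds=tuple(tied), notes=tuple(notes)
    )


def estimate_mosaic_fraction(
    source,
    kind: ScenarioKind,
    sig: Optional[FFSignature] = None,
) -> Tuple[float, str]:
    """Mosaic-fraction estimate for a fixed scenario kind.

    With a :class:`RegressionResult` and a maternal meiotic trisomy a
    closed form applies: MI slopes are (1 - m/2, -m/2) (or the mirrored
    branch), so ``slope_alpha + slope_beta = +/-(1 - m)`` and
    ``m = 1 - |slope_alpha + slope_beta|``; MII slopes are (1 + m/2, m/2),
    giving ``m = |slope_alpha + slope_beta| - 1``.  Combining both slopes
    halves the estimator variance relative to using slope_beta alone
    (``m = -2 slope_beta`` on the M1 branch).  Otherwise a 1-D least
    squares on the signature is used.  The estimate is clipped to [0, 1].
    """
    if kind not in ABNORMAL_KINDS:
        raise ValueError(f"{kind.value} has no mosaic parameter")

    if isinstance(source, RegressionResult):
        if kind in (ScenarioKind.TRI_MAT_MEI1, ScenarioKind.TRI_MAT_MEI2):
            if not source.defined or source.slope_alpha is None:
                raise ValueError("slopes undefined")
            total = abs(source.slope_alpha + source.slope_beta)
            if kind is ScenarioKind.TRI_MAT_MEI1:
                m = 1.0 - total
            else:
                m = total - 1.0
            return float(np.clip(m, 0.0, 1.0)), "closed form from slopes"
        if sig is None:
            raise ValueError(
                "signature required for kinds without a slope closed form"
            )
        source = sig

    if not isinstance(source, FFSignature):
        raise TypeError("source must be a FFSignature or RegressionResult")

    obs = _sig_vector(source)
    weights = _sig_weights(source, 1e-4)

    def loss(m: float) -> float:
        best = math.inf
        for tm in ("M1", "M2"):
            for tp in ("P1", "P2"):
                _, d = _fit_f(
                    obs,
                    weights,
                    lambda f, tm=tm, tp=tp: Scenario(
                        kind, f, tm, tp, mosaic_fraction=m
                    ),
                    None,
                    0.0,
                )
                best = min(best, d)
        return best

    res = minimize_scalar(
        loss, bounds=(1e-3, 1.0), method="bounded",
        options={"xatol": 1e-3, "maxiter": 40},
    )
    return float(np.clip(res.x, 0.0, 1.0)), "least squares on signature"


@dataclass
class AnomalyCall:
    """Aggregate QC verdict for one sample."""

    alert: AlertResult
    slope_flag: Optional[SlopeFlag]
    classification: ClassificationResult
    transmitted_maternal: str
    notes: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "alert": self.alert.to_dict(),
            "slope_flag": (
                self.slope_flag.to_dict() if self.slope_flag else None
            ),
            "classification": self.classification.to_dict(),
            "transmitted_maternal": self.transmitted_maternal,
            "notes": list(self.notes),
        }


def _transmitted_call(sig: FFSignature) -> str:
    alpha = sig.ff_t4[Subtype.T4_ALPHA]
    beta = sig.ff_t4[Subtype.T4_BETA]
    if not (alpha.available and beta.available):
        return "NONE"
    sa, na = _conformity(alpha, sig)
    sb, nb = _conformity(beta, sig)
    if sa and nb and not sb:
        return "M1"
    if sb and na and not sa:
        return "M2"
    if sa and sb:
        return "AMBIGUOUS"
    return "NONE"


def call_sample(
    sig: FFSignature,
    reg: Optional[RegressionResult] = None,
    min_snps: int = 5,
    slope_tolerance: float = 0.15,
) -> AnomalyCall:
    """Run the full QC stack on one sample's signature (+ optional slopes)."""
    alert = alert_from_signature(sig, min_snps=min_snps)
    flag = slope_flags(reg, slope_tolerance) if reg is not None else None
    classification = classify_scenario(sig, reg)
    notes: List[str] = list(classification.notes)
    if sig.xxy_flag:
        notes.append(
            "male Y signal with a paternal X haplotype: possible 47,XXY"
        )
    return AnomalyCall(
        alert=alert,
        slope_flag=flag,
        classification=classification,
        transmitted_maternal=_transmitted_call(sig),
        notes=tuple(notes),
    )
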