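"""In-silico dilution of count tables and the Type-4 vs Type-1 regression.

Reducing the effective fetal fraction by mixing plasma counts with matched
maternal counts, then regressing the two signed Type-4 FF estimates against
the Type-1 estimate, turns a single noisy allelic-balance comparison into a
slope: +1/0 (M1 transmitted) or 0/-1 (M2 transmitted) in a normal pregnancy,
and characteristically shifted values for aneuploidies and UPDs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .panel import Panel, Subtype
from .signature import AlleleCountTable, compute_signature

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS: Tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)

__all__ = [
    "DEFAULT_PROPORTIONS",
    "RegressionResult",
    "dilute_counts",
    "regression_series",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def dilute_counts(
    sample: AlleleCountTable,
    maternal: AlleleCountTable,
    p: float,
    mode: str = "round",
    rng: Optional[np.random.Generator] = None,
) -> AlleleCountTable:
    """Mix sample and maternal counts so mixing weights act on frequencies.

    Maternal counts are depth-rescaled per SNP before mixing:
    ``mixed = p * n_sample + (1-p) * n_maternal * depth_sample/depth_maternal``.

    Modes: ``round`` (deterministic, half away from zero), ``exact`` (float
    counts, for oracle-exact studies), ``binomial`` (multinomial resampling
    at the sample depth, for noise studies).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p outside [0,1]")
    if mode not in ("round", "exact", "binomial"):
        raise ValueError(f"unknown dilution mode {mode!r}")
    if mode == "binomial" and rng is None:
        rng = np.random.default_rng()

    shared = [s for s in sample.snp_ids if s in maternal]
    dropped = (set(sample.snp_ids) | set(maternal.snp_ids)) - set(shared)
    if dropped:
        logger.warning(
            "%d SNPs present in only one table, excluded from dilution",
            len(dropped),
        )

    mixed: Dict[str, np.ndarray] = {}
    for snp_id in shared:
        ns = sample.counts(snp_id)
        nm = maternal.counts(snp_id)
        ds, dm = ns.sum(), nm.sum()
        if dm <= 0 and p < 1.0:
            # expected for Y loci (no maternal Y material)
            logger.debug("%s: zero maternal depth, excluded", snp_id)
            continue
        scaled_m = nm * (ds / dm) if dm > 0 else np.zeros(4)
        raw = p * ns + (1.0 - p) * scaled_m
        if mode == "exact":
            mixed[snp_id] = raw
        elif mode == "round":
            mixed[snp_id] = _round_half_away(raw)
        else:
            total = raw.sum()
            if total <= 0:
                mixed[snp_id] = np.zeros(4)
            else:
                mixed[snp_id] = rng.multinomial(
                    int(round(total)), raw / total
                ).astype(float)
    return AlleleCountTable(mixed)


@dataclass
class RegressionResult:
    """Per-dilution FF triples and the fitted Type-4-vs-Type-1 slopes."""

    proportions: Tuple[float, ...]
    ff_t1: Tuple[float, ...]
    ff_t4_alpha: Tuple[float, ...]
    ff_t4_beta: Tuple[float, ...]
    slope_alpha: Optional[float] = None
    slope_beta: Optional[float] = None
    intercept_alpha: Optional[float] = None
    intercept_beta: Optional[float] = None
    r2_alpha: Optional[float] = None
    r2_beta: Optional[float] = None
    slope_alpha_origin: Optional[float] = None
    slope_beta_origin: Optional[float] = None
    defined: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "proportions": list(self.proportions),
            "ff_t1": list(self.ff_t1),
            "ff_t4_alpha": list(self.ff_t4_alpha),
            "ff_t4_beta": list(self.ff_t4_beta),
            "slope_alpha": self.slope_alpha,
            "slope_beta": self.slope_beta,
            "intercept_alpha": self.intercept_alpha,
            "intercept_beta": self.intercept_beta,
            "r2_alpha": self.r2_alpha,
            "r2_beta": self.r2_beta,
            "slope_alpha_origin": self.slope_alpha_origin,
            "slope_beta_origin": self.slope_beta_origin,
            "defined": self.defined,
            "note": self.note,
        }


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Slope, intercept, R-squared of y ~ x (free intercept)."""
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def regression_series(
    sample: AlleleCountTable,
    maternal: AlleleCountTable,
    panel: Panel,
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    mode: str = "round",
    rng: Optional[np.random.Generator] = None,
) -> RegressionResult:
    """FF estimates along the dilution ladder, plus OLS slopes.

    Proportions must be strictly decreasing in (0, 1]; at least 3 points
    are required for a fit.  Both free-intercept and through-origin slopes
    are reported.
    """
    proportions = tuple(float(p) for p in proportions)
    if len(proportions) < 3:
        raise ValueError("need at least 3 dilution proportions")
    if any(not (0.0 < p <= 1.0) for p in proportions):
        raise ValueError("proportions must lie in (0, 1]")
    if any(b >= a for a, b in zip(proportions, proportions[1:])):
        raise ValueError("proportions must be strictly decreasing")

    t1: List[float] = []
    t4a: List[float] = []
    t4b: List[float] = []
    for p in proportions:
        table = sample if p == 1.0 else dilute_counts(
            sample, maternal, p, mode=mode, rng=rng
        )
        sig = compute_signature(table, panel)
        for est, dest in (
            (sig.ff_t1, t1),
            (sig.ff_t4[Subtype.T4_ALPHA], t4a),
            (sig.ff_t4[Subtype.T4_BETA], t4b),
        ):
            dest.append(est.value if est.available else math.nan)

    x = np.asarray(t1)
    ya = np.asarray(t4a)
    yb = np.asarray(t4b)
    result = RegressionResult(
        proportions=proportions,
        ff_t1=tuple(t1),
        ff_t4_alpha=tuple(t4a),
        ff_t4_beta=tuple(t4b),
    )
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(ya)) or np.any(
        ~np.isfinite(yb)
    ):
        result.defined = False
        result.note = "missing FF estimates along the ladder"
        return result
    if x.max() - x.min() < 1e-12:
        result.defined = False
        result.note = "degenerate Type-1 range (no fetal signal?)"
        return result

    result.slope_alpha, result.intercept_alpha, result.r2_alpha = _ols(x, ya)
    result.slope_beta, result.intercept_beta, result.r2_beta = _ols(x, yb)
    sxx = float(np.sum(x * x))
    result.slope_alpha_origin = float(np.sum(x * ya) / sxx)
    result.slope_beta_origin = float(np.sum(x * yb) / sxx)
    return result
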