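"""Synthetic composite-sample generator.

Reproduces the mixture experiments behind the method validation: a panel of
phased SNPs, a contributor mixture (mother + fetal clones), and multinomial
consensus-read sampling with a symmetric per-read substitution error.

Molecular (barcode-consensus) depth is simulated, not raw read depth: the
per-locus depth is Poisson around ``mean depth x locus copy mass``, so a
trisomic or monosomic scenario shifts coverage exactly as the mixture model
predicts, and Y loci are covered only in male-fetus scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .oracle import (
    Contributor,
    Scenario,
    contributors_for_scenario,
    expected_allele_freqs,
    expected_locus_mass,
    mother_only_contributors,
)
from .panel import Panel, SnpLocus, SnpType, Subtype, build_panel
from .signature import ALLELES, ALLELE_INDEX, AlleleCountTable

__all__ = [
    "DEFAULT_COMPOSITION",
    "SimConfig",
    "SimBundle",
    "simulate_panel",
    "simulate_counts",
    "simulate_case",
]

#: Default panel composition: 389 X-chromosome SNPs plus 4 Y loci.  The
#: per-type split of the real panel is not published; since Type-4 SNPs are
#: the basis of relative haplotype dosage, panels are designed to maximise
#: them, and the Type-4-vs-Type-1 slope precision scales with their count.
DEFAULT_COMPOSITION: Dict[str, int] = {
    "T1": 25,
    "T2": 25,
    "T3_P1": 12,
    "T3_P2": 12,
    "T4_ALPHA": 155,
    "T4_BETA": 155,
    "T5": 5,
    "Y": 4,
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs: panel composition, depth law, error model."""

    composition: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    mean_depth: float = 640.0
    error_rate: float = 0.001
    depth_law: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate outside [0, 0.05]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.depth_law not in ("poisson", "negbin"):
            raise ValueError(f"unknown depth law {self.depth_law!r}")
        for key, n in self.composition.items():
            if n < 0:
                raise ValueError(f"negative count for class {key}")


@dataclass
class SimBundle:
    """One simulated case: panel, plasma and maternal tables, plus truth."""

    panel: Panel
    plasma: AlleleCountTable
    maternal: AlleleCountTable
    truth: dict


# genotype templates per class: (maternal pair, paternal pair) as index
# patterns into a shuffled 4-nucleotide alphabet (0/1 distinct alleles)
_CLASS_TEMPLATES = {
    "T1": ((0, 0), (1, 1)),
    "T2": ((0, 0), (0, 0)),
    "T3_P1": ((0, 0), (1, 0)),
    "T3_P2": ((0, 0), (0, 1)),
    "T4_ALPHA": ((0, 1), (0, 0)),
    "T4_BETA": ((0, 1), (1, 1)),
    "T5": ((0, 1), (0, 1)),
}


def simulate_panel(
    config: SimConfig = SimConfig(), seed: int = 0
) -> Panel:
    """Random panel with the requested per-class composition.

    Deterministic per seed; every generated locus round-trips through
    classification into its requested class.
    """
    rng = np.random.default_rng(seed)
    loci = []
    pos = 0
    idx = 0
    for class_key, n in config.composition.items():
        for _ in range(n):
            pos += int(rng.integers(500, 5000))
            idx += 1
            if class_key == "Y":
                loci.append(
                    SnpLocus(
                        snp_id=f"y{idx:04d}",
                        chrom="Y",
                        pos=pos,
                        is_y_locus=True,
                    )
                )
                continue
            if class_key not in _CLASS_TEMPLATES:
                raise ValueError(f"unknown panel class {class_key!r}")
            alphabet = rng.permutation(np.asarray(list("ACGT")))
            mat_idx, pat_idx = _CLASS_TEMPLATES[class_key]
            loci.append(
                SnpLocus(
                    snp_id=f"snp{idx:04d}",
                    chrom="X",
                    pos=pos,
                    maternal_hap=tuple(alphabet[i] for i in mat_idx),
                    paternal_hap=tuple(alphabet[i] for i in pat_idx),
                )
            )
    return build_panel(loci)


def _draw_depth(rng, mean: float, config: SimConfig) -> int:
    if mean <= 0:
        return 0
    if config.depth_law == "poisson":
        return int(rng.poisson(mean))
    # negative binomial with mean `mean` and dispersion r
    r = config.negbin_dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_counts(
    panel: Panel,
    contributors: Sequence[Contributor],
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> AlleleCountTable:
    """Draw a consensus-count table for one sample.

    Per locus: depth ~ depth law around ``mean_depth x locus mass``;
    observed allele probabilities are the exact mixture frequencies passed
    through the symmetric substitution error
    ``p_obs = (1-e) p_true + (e/3)(1 - p_true)``; counts ~ multinomial.
    """
    rng = np.random.default_rng(seed)
    e = config.error_rate
    counts: Dict[str, np.ndarray] = {}
    for locus in panel:
        mass = expected_locus_mass(contributors, locus)
        depth = _draw_depth(rng, config.mean_depth * mass, config)
        if depth == 0:
            counts[locus.snp_id] = np.zeros(4)
            continue
        p_true = np.zeros(4)
        for allele, freq in expected_allele_freqs(
            contributors, locus
        ).items():
            p_true[ALLELE_INDEX[allele]] += freq
        p_obs = (1.0 - e) * p_true + (e / 3.0) * (1.0 - p_true)
        p_obs /= p_obs.sum()
        counts[locus.snp_id] = rng.multinomial(depth, p_obs).astype(float)
    return AlleleCountTable(counts)


def simulate_case(
    scenario: Scenario,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    panel: Optional[Panel] = None,
) -> SimBundle:
    """Simulate a full case: plasma + matched maternal-only count tables."""
    seq = np.random.SeedSequence(seed)
    panel_seq, plasma_seq, maternal_seq = seq.spawn(3)
    if panel is None:
        panel = simulate_panel(config, seed=panel_seq)
    contributors = contributors_for_scenario(scenario)
    plasma = simulate_counts(panel, contributors, config, seed=plasma_seq)
    maternal = simulate_counts(
        panel, mother_only_contributors(), config, seed=maternal_seq
    )
    truth = {
        "scenario": scenario.to_dict(),
        "seed": seed,
        "mean_depth": config.mean_depth,
        "error_rate": config.error_rate,
    }
    return SimBundle(panel=panel, plasma=plasma, maternal=maternal, truth=truth)
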