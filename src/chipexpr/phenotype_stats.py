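"""Body-length effect sizes for the target-gene phenotype screen.

Glass' Δ standardizes the body-size change of a mutant or RNAi knockdown
arm by the *control* group's sample standard deviation:

    Δ = (mean_control - mean_treatment) / sd_control

so that smaller bodies give a positive Δ.  An optional Welch t-test p-value
is provided for convenience; significance calling is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_tables import PhenotypeTable

__all__ = ["EffectSizeResult", "glass_delta", "screen_effect_sizes"]


@dataclass
class EffectSizeResult:
    genotype: str
    n: int
    mean_um: float
    sd_um: float
    normalized_mean: float  # control = 1
    glass_delta: float
    welch_p: float | None = None


def glass_delta(
    treatment: Sequence[float],
    control: Sequence[float],
    genotype: str = "",
    flip_sign: bool = False,
    welch: bool = True,
) -> EffectSizeResult:
    """Glass' effect size of a treatment arm against the control arm.

    Uses the sample SD (n-1 denominator) of the control group.  With the
    default sign convention a treatment mean below the control mean yields
    Δ > 0 (smaller bodies, larger effect); ``flip_sign`` inverts this.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(c) < 2:
        raise ValueError(f"need >=2 control measurements, got {len(c)}")
    if len(t) < 1:
        raise ValueError("empty treatment arm")
    sd_c = float(c.std(ddof=1))
    if sd_c == 0:
        raise ValueError("control SD is zero; Glass' delta undefined")
    delta = (float(c.mean()) - float(t.mean())) / sd_c
    if flip_sign:
        delta = -delta
    welch_p = None
    if welch and len(t) >= 2:
        welch_p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
    return EffectSizeResult(
        genotype=genotype,
        n=len(t),
        mean_um=float(t.mean()),
        sd_um=float(t.std(ddof=1)) if len(t) >= 2 else float("nan"),
        normalized_mean=float(t.mean()) / float(c.mean()),
        glass_delta=delta,
        welch_p=welch_p,
    )


def screen_effect_sizes(
    table: PhenotypeTable,
    control_genotype: str,
    flip_sign: bool = False,
) -> list[EffectSizeResult]:
    """Glass' Δ for every non-control genotype in a phenotype table."""
    genotypes = table.genotypes()
    if control_genotype not in genotypes:
        raise ValueError(f"control genotype {control_genotype!r} not in table")
    control = table.lengths(control_genotype)
    return [
        glass_delta(table.lengths(g), control, genotype=g, flip_sign=flip_sign)
        for g in genotypes
        if g != control_genotype
    ]
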